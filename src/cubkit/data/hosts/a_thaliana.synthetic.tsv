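# Synthetic snapshot: approximate codon usage of a_thaliana, frequency per
# thousand codons over all 64 codons, written from general knowledge of the
# organism's published usage (NOT an official database export); renormalised
# to sum 1000 on load. Replace with a real table for production comparisons.
codon	per_thousand
AAA	30.8
AAC	20.9
AAG	32.7
AAT	22.3
ACA	15.7
ACC	10.3
ACG	7.7
ACT	17.5
AGA	19.0
AGC	11.3
AGG	11.0
AGT	14.0
ATA	12.6
ATC	18.5
ATG	24.5
ATT	21.5
CAA	19.4
CAC	8.7
CAG	15.2
CAT	13.8
CCA	16.1
CCC	5.3
CCG	8.6
CCT	18.8
CGA	6.3
CGC	3.8
CGG	4.9
CGT	9.0
CTA	10.0
CTC	16.1
CTG	9.8
CTT	24.1
GAA	34.3
GAC	17.2
GAG	32.2
GAT	36.5
GCA	17.5
GCC	10.3
GCG	8.6
GCT	28.3
GGA	24.2
GGC	9.2
GGG	10.2
GGT	22.2
GTA	9.9
GTC	12.8
GTG	17.4
GTT	27.2
TAA	0.9
TAC	13.7
TAG	0.5
TAT	14.6
TCA	18.3
TCC	11.2
TCG	9.3
TCT	25.2
TGA	1.2
TGC	7.2
TGG	12.5
TGT	10.5
TTA	12.8
TTC	20.7
TTG	20.9
TTT	21.8
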