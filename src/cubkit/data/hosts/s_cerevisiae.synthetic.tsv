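# Synthetic snapshot: approximate codon usage of s_cerevisiae, frequency per
# thousand codons over all 64 codons, written from general knowledge of the
# organism's published usage (NOT an official database export); renormalised
# to sum 1000 on load. Replace with a real table for production comparisons.
codon	per_thousand
AAA	41.9
AAC	24.8
AAG	30.8
AAT	35.7
ACA	17.8
ACC	12.7
ACG	8.0
ACT	20.3
AGA	21.3
AGC	9.8
AGG	9.2
AGT	14.2
ATA	17.8
ATC	17.2
ATG	20.9
ATT	30.1
CAA	27.3
CAC	7.8
CAG	12.1
CAT	13.6
CCA	18.3
CCC	6.8
CCG	5.3
CCT	13.5
CGA	3.0
CGC	2.6
CGG	1.7
CGT	6.4
CTA	13.4
CTC	5.4
CTG	10.5
CTT	12.3
GAA	45.6
GAC	20.2
GAG	19.2
GAT	37.6
GCA	16.2
GCC	12.6
GCG	6.2
GCT	21.2
GGA	10.9
GGC	9.8
GGG	6.0
GGT	23.9
GTA	11.8
GTC	11.8
GTG	10.8
GTT	22.1
TAA	1.1
TAC	14.8
TAG	0.5
TAT	18.8
TCA	18.7
TCC	14.2
TCG	8.6
TCT	23.5
TGA	0.7
TGC	4.8
TGG	10.4
TGT	8.1
TTA	26.2
TTC	18.4
TTG	27.2
TTT	26.1
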