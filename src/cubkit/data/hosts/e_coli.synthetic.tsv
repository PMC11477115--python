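# Synthetic snapshot: approximate codon usage of e_coli, frequency per
# thousand codons over all 64 codons, written from general knowledge of the
# organism's published usage (NOT an official database export); renormalised
# to sum 1000 on load. Replace with a real table for production comparisons.
codon	per_thousand
AAA	33.6
AAC	21.7
AAG	10.3
AAT	17.7
ACA	7.1
ACC	23.4
ACG	14.4
ACT	9.0
AGA	2.1
AGC	16.1
AGG	1.2
AGT	8.8
ATA	4.2
ATC	25.1
ATG	27.9
ATT	30.3
CAA	15.3
CAC	9.7
CAG	28.8
CAT	12.9
CCA	8.4
CCC	5.5
CCG	23.2
CCT	7.0
CGA	3.6
CGC	22.0
CGG	5.4
CGT	20.9
CTA	3.9
CTC	11.0
CTG	52.6
CTT	11.0
GAA	39.4
GAC	19.1
GAG	17.8
GAT	32.1
GCA	20.1
GCC	25.5
GCG	33.6
GCT	15.3
GGA	8.0
GGC	29.6
GGG	11.1
GGT	24.7
GTA	10.8
GTC	15.3
GTG	26.4
GTT	18.3
TAA	2.0
TAC	12.2
TAG	0.2
TAT	16.2
TCA	7.2
TCC	8.6
TCG	8.9
TCT	8.4
TGA	1.0
TGC	6.4
TGG	15.2
TGT	5.2
TTA	13.9
TTC	16.6
TTG	13.7
TTT	22.2
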