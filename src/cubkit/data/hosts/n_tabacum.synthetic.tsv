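# Synthetic snapshot: approximate codon usage of n_tabacum, frequency per
# thousand codons over all 64 codons, written from general knowledge of the
# organism's published usage (NOT an official database export); renormalised
# to sum 1000 on load. Replace with a real table for production comparisons.
codon	per_thousand
AAA	33.7
AAC	19.0
AAG	29.7
AAT	25.8
ACA	16.8
ACC	10.6
ACG	6.3
ACT	19.8
AGA	19.7
AGC	10.5
AGG	12.0
AGT	14.1
ATA	13.1
ATC	15.8
ATG	23.6
ATT	26.5
CAA	21.9
CAC	8.6
CAG	14.7
CAT	14.3
CCA	17.8
CCC	8.9
CCG	5.8
CCT	19.1
CGA	5.8
CGC	4.4
CGG	4.2
CGT	7.5
CTA	9.7
CTC	13.5
CTG	12.1
CTT	24.5
GAA	34.2
GAC	16.4
GAG	28.3
GAT	31.7
GCA	17.3
GCC	11.6
GCG	5.6
GCT	26.1
GGA	21.6
GGC	11.8
GGG	10.6
GGT	21.5
GTA	10.5
GTC	10.3
GTG	15.4
GTT	25.8
TAA	1.2
TAC	12.5
TAG	0.5
TAT	15.4
TCA	17.7
TCC	11.5
TCG	7.4
TCT	21.8
TGA	1.1
TGC	6.5
TGG	12.3
TGT	8.0
TTA	12.6
TTC	19.2
TTG	22.9
TTT	23.6
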