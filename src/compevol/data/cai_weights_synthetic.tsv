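codon	w
AAA	0.4
AAC	1.0
AAG	1.0
AAT	0.4
ACA	0.2222
ACC	0.4
ACG	1.0
ACT	0.2857
AGA	0.1538
AGC	0.2857
AGG	0.2857
AGT	0.1538
ATA	0.2857
ATC	1.0
ATG	1.0
ATT	0.4
CAA	0.4
CAC	1.0
CAG	1.0
CAT	0.4
CCA	0.2222
CCC	0.4
CCG	1.0
CCT	0.2857
CGA	0.1818
CGC	0.4
CGG	1.0
CGT	0.2222
CTA	0.1538
CTC	0.2857
CTG	0.4
CTT	0.1818
GAA	0.4
GAC	1.0
GAG	1.0
GAT	0.4
GCA	0.2222
GCC	0.4
GCG	1.0
GCT	0.2857
GGA	0.2222
GGC	0.4
GGG	1.0
GGT	0.2857
GTA	0.2222
GTC	0.4
GTG	1.0
GTT	0.2857
TAC	1.0
TAT	0.4
TCA	0.1818
TCC	0.4
TCG	1.0
TCT	0.2222
TGC	1.0
TGG	1.0
TGT	0.4
TTA	0.2222
TTC	1.0
TTG	1.0
TTT	0.4
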