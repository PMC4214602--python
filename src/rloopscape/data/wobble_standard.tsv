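# anticodon	codons (comma-separated, DNA alphabet)
AAA	TTT,TTC,TTA
AAC	GTT,GTC,GTA
AAG	CTT,CTC,CTA
AAU	ATT,ATC,ATA
ACA	TGT,TGC
ACC	GGT,GGC,GGA
ACG	CGT,CGC,CGA
ACU	AGT,AGC,AGA
AGA	TCT,TCC,TCA
AGC	GCT,GCC,GCA
AGG	CCT,CCC,CCA
AGU	ACT,ACC,ACA
AUA	TAT,TAC
AUC	GAT,GAC,GAA
AUG	CAT,CAC,CAA
AUU	AAT,AAC,AAA
CAA	TTG
CAC	GTG
CAG	CTG
CAU	ATG
CCA	TGG
CCC	GGG
CCG	CGG
CCU	AGG
CGA	TCG
CGC	GCG
CGG	CCG
CGU	ACG
CUC	GAG
CUG	CAG
CUU	AAG
GAA	TTC,TTT
GAC	GTC,GTT
GAG	CTC,CTT
GAU	ATC,ATT
GCA	TGC,TGT
GCC	GGC,GGT
GCG	CGC,CGT
GCU	AGC,AGT
GGA	TCC,TCT
GGC	GCC,GCT
GGG	CCC,CCT
GGU	ACC,ACT
GUA	TAC,TAT
GUC	GAC,GAT
GUG	CAC,CAT
GUU	AAC,AAT
UAA	TTA,TTG
UAC	GTA,GTG
UAG	CTA,CTG
UAU	ATA,ATG
UCA	TGG
UCC	GGA,GGG
UCG	CGA,CGG
UCU	AGA,AGG
UGA	TCA,TCG
UGC	GCA,GCG
UGG	CCA,CCG
UGU	ACA,ACG
UUC	GAA,GAG
UUG	CAA,CAG
UUU	AAA,AAG
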