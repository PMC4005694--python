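# Default tRNA isoacceptor inventory for Methanothermobacter thermautotrophicus.
# One line per isoacceptor: anticodon <TAB> gene copy number <TAB> decoded codons.
# Ser and Arg anticodons follow the genome annotation (the tRNA-Ser GGA gene is
# duplicated); the remaining families use a generic archaeal layout with a G34
# isoacceptor reading NNC/NNT and a T34 isoacceptor reading NNA/NNG (C34 reads
# NNG exactly; the Ile AUA codon has a dedicated one-codon reader, as its
# decoding relies on a modified wobble base that must not read AUG).
# Decoding is configuration, not inference: edit this table for other genomes.
GGC	1	GCC,GCT
TGC	1	GCA,GCG
GCG	1	CGC,CGT
TCG	1	CGA,CGG
CCT	1	AGG
TCT	1	AGA,AGG
GTT	1	AAC,AAT
GTC	1	GAC,GAT
GCA	1	TGC,TGT
CTG	1	CAG
TTG	1	CAA,CAG
CTC	1	GAG
TTC	1	GAA,GAG
GCC	1	GGC,GGT
TCC	1	GGA,GGG
GTG	1	CAC,CAT
GAT	1	ATC,ATT
TAT	1	ATA
GAG	1	CTC,CTT
TAG	1	CTA,CTG
CAA	1	TTG
TAA	1	TTA,TTG
CTT	1	AAG
TTT	1	AAA,AAG
GAA	1	TTC,TTT
GGG	1	CCC,CCT
TGG	1	CCA,CCG
GGA	2	TCC,TCT
TGA	1	TCA,TCG
GCT	1	AGC,AGT
GGT	1	ACC,ACT
TGT	1	ACA,ACG
GTA	1	TAC,TAT
GAC	1	GTC,GTT
TAC	1	GTA,GTG
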