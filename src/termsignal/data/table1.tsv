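stop_codon	amino_acid	anticodon
TAA	Glu	TTC
TAA	Gln	TTG
TAA	Lys	TTT
TAA	Leu	TAA
TAA	Ser	TGA
TAA	Tyr	GTA
TAG	Glu	CTC
TAG	Gln	CTG
TAG	Lys	CTT
TAG	Leu	CAA
TAG	Trp	CCA
TAG	Ser	CGA
TAG	Tyr	GTA
TGA	Gly	TCC
TGA	Arg	TCG
TGA	Arg	TCT
TGA	Leu	TAA
TGA	Ser	TGA
TGA	Trp	CCA
TGA	Cys	GCA
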