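gene_symbol	full_name	signed_fc	direction
RARRES3	Retinoic acid receptor responder (tazarotene induced) 3	1.75	up_in_young
SFRP4	Secreted frizzled-related protein 4	1.71	up_in_young
SCUBE2	Signal peptide, CUB domain, EGF-like 2	1.83	up_in_young
NAT1	N-acetyltransferase 1 (arylamine N-acetyltransferase)	1.51	up_in_young
COMP	Cartilage oligomeric matrix protein	1.56	up_in_young
ANXA3	Annexin A3	-2.06	up_in_old
PROM1	Prominin 1	-2.27	up_in_old
FGF13	Fibroblast growth factor 13	-1.68	up_in_old
TUBB2B	Tubulin, beta 2B	-1.64	up_in_old
WIF1	WNT inhibitory factor 1	-2.10	up_in_old
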