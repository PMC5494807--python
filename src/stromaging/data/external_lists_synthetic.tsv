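gene_symbol	direction	dataset_id
RARRES3	up_in_young	stroma-metadata-synthetic
SFRP4	up_in_young	stroma-metadata-synthetic
SCUBE2	up_in_young	stroma-metadata-synthetic
NAT1	up_in_young	stroma-metadata-synthetic
COMP	up_in_young	stroma-metadata-synthetic
ANXA3	up_in_old	stroma-metadata-synthetic
PROM1	up_in_old	stroma-metadata-synthetic
FGF13	up_in_old	stroma-metadata-synthetic
TUBB2B	up_in_old	stroma-metadata-synthetic
WIF1	up_in_old	stroma-metadata-synthetic
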