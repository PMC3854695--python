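gene_id	dataset_id	category	printed_label
AT1G29660	early_colxcvi	biallelic	biallelic
AT1G72260	early_colxcvi	maternal	maternal
AT2G47115	early_colxcvi	maternal	maternal
AT5G62210	early_colxcvi	maternal	maternal
AT3G20520	early_colxcvi	maternal	maternal
AT2G17710	early_colxcvi	biallelic	biallelic
AT3G21500	early_colxcvi	maternal	maternal
AT2G01520	early_colxcvi	maternal_bias	maternal bias
AT1G20680	early_colxcvi	maternal	maternal
AT5G51950	early_colxcvi	maternal_bias	maternal bias
AT1G29050	early_colxcvi	no_snp_coverage	no SNPs covered
AT3G26790	early_colxcvi	paternal	early PEG
AT1G29660	torpedo_colxler	accession_bias	Ler bias
AT1G72260	torpedo_colxler	maternal	maternal
AT2G47115	torpedo_colxler	not_expressed	not expressed
AT5G62210	torpedo_colxler	biallelic	biallelic
AT3G20520	torpedo_colxler	maternal_bias	maternal bias
AT2G17710	torpedo_colxler	maternal_bias	maternal bias
AT3G21500	torpedo_colxler	maternal	maternal
AT2G01520	torpedo_colxler	maternal	maternal
AT1G20680	torpedo_colxler	maternal	maternal
AT5G51950	torpedo_colxler	maternal	maternal
AT1G29050	torpedo_colxler	maternal_bias	maternal bias
AT3G26790	torpedo_colxler	biallelic	biallelic
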