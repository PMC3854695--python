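gene_id	sample_id	call
AT1G29660	CxL_24_6x	maternal_only
AT1G29660	LxC_24_6x	maternal_only
AT1G72260	CxL_24_6x	maternal_only
AT1G72260	LxC_24_6x	maternal_only
AT2G47115	CxL_24_6x	maternal_only
AT2G47115	LxC_24_6x	maternal_only
AT5G62210	CxL_24_6x	maternal_only
AT5G62210	LxC_24_6x	maternal_only
AT3G20520	CxL_24_6x	maternal_only
AT3G20520	LxC_24_6x	maternal_only
AT2G17710	CxL_24_6x	maternal_only
AT2G17710	LxC_24_6x	maternal_only
AT3G21500	CxL_24_6x	maternal_only
AT3G21500	LxC_24_6x	maternal_only
AT2G01520	CxL_24_6x	maternal_only
AT2G01520	LxC_24_6x	not_detected
AT1G20680	CxL_24_6x	maternal_only
AT1G20680	LxC_24_6x	not_detected
AT5G51950	CxL_24_6x	maternal_only
AT5G51950	LxC_24_6x	not_detected
AT1G29050	CxL_24_6x	maternal_only
AT1G29050	LxC_24_6x	not_detected
AT4G11960	CxL_24_6x	not_detected
AT4G11960	LxC_24_6x	not_detected
AT3G26790	CxL_24_6x	paternal_only
AT3G26790	LxC_24_6x	not_detected
AT2G20160	CxL_24_6x	biallelic
AT2G20160	LxC_24_6x	not_detected
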