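gene_id	sample_id	call
AT1G20680	LxfieC_24	maternal_only
AT1G20680	LxmetC_24	maternal_only
AT1G20680	fieCxL_24	maternal_only
AT1G20680	fieCxL_gl	maternal_only
AT1G29050	LxfieC_24	maternal_only
AT1G29050	LxmetC_24	maternal_only
AT1G29050	fieCxL_24	maternal_only
AT1G29050	fieCxL_gl	maternal_only
AT1G29660	LxfieC_24	maternal_only
AT1G29660	LxmetC_24	maternal_only
AT1G29660	fieCxL_24	maternal_bias
AT1G29660	fieCxL_gl	biallelic
AT1G72260	LxfieC_24	maternal_only
AT1G72260	LxmetC_24	maternal_only
AT1G72260	fieCxL_24	maternal_bias
AT1G72260	fieCxL_gl	maternal_bias
AT2G01520	LxfieC_24	maternal_only
AT2G01520	LxmetC_24	maternal_only
AT2G01520	fieCxL_24	maternal_only
AT2G01520	fieCxL_gl	maternal_only
AT2G17710	LxfieC_24	maternal_only
AT2G17710	LxmetC_24	maternal_only
AT2G17710	fieCxL_24	maternal_only
AT2G17710	fieCxL_gl	maternal_only
AT2G47115	LxfieC_24	maternal_only
AT2G47115	LxmetC_24	maternal_only
AT2G47115	fieCxL_24	maternal_only
AT2G47115	fieCxL_gl	maternal_only
AT3G20520	LxfieC_24	maternal_only
AT3G20520	LxmetC_24	maternal_only
AT3G20520	fieCxL_24	maternal_only
AT3G20520	fieCxL_gl	maternal_only
AT3G21500	LxfieC_24	maternal_only
AT3G21500	LxmetC_24	maternal_only
AT3G21500	fieCxL_24	maternal_only
AT3G21500	fieCxL_gl	maternal_only
AT3G26790	LxfieC_24	maternal_only
AT3G26790	LxmetC_24	not_detected
AT5G51950	LxfieC_24	maternal_only
AT5G51950	LxmetC_24	maternal_only
AT5G51950	fieCxL_24	maternal_only
AT5G51950	fieCxL_gl	maternal_only
AT5G62210	LxfieC_24	maternal_only
AT5G62210	LxmetC_24	maternal_only
AT5G62210	fieCxL_24	maternal_only
AT5G62210	fieCxL_gl	maternal_only
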