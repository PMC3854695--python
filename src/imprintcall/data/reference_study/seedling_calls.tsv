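gene_id	sample_id	call
AT1G29660	CxL_sdl	biallelic
AT1G29660	LxC_sdl	biallelic
AT1G72260	CxL_sdl	biallelic
AT1G72260	LxC_sdl	biallelic
AT2G47115	CxL_sdl	not_detected
AT2G47115	LxC_sdl	not_detected
AT5G62210	CxL_sdl	biallelic
AT5G62210	LxC_sdl	biallelic
AT3G20520	CxL_sdl	biallelic
AT3G20520	LxC_sdl	biallelic
AT2G17710	CxL_sdl	biallelic
AT2G17710	LxC_sdl	biallelic
AT3G21500	CxL_sdl	not_detected
AT3G21500	LxC_sdl	not_detected
AT2G01520	CxL_sdl	biallelic
AT2G01520	LxC_sdl	biallelic
AT1G20680	CxL_sdl	biallelic
AT1G20680	LxC_sdl	biallelic
AT5G51950	CxL_sdl	biallelic
AT5G51950	LxC_sdl	biallelic
AT1G29050	CxL_sdl	biallelic
AT1G29050	LxC_sdl	biallelic
AT3G26790	CxL_sdl	biallelic
AT3G26790	LxC_sdl	biallelic
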