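sample_id	maternal_accession	paternal_accession	maternal_genotype	paternal_genotype	stage	replicate	wash	tissue	run_batch
CxL_24_r1	Col-0	Ler	WT	WT	two_four_cell	1	x1	embryo	run1
CxL_24_r2	Col-0	Ler	WT	WT	two_four_cell	2	x1	embryo	run1
LxC_24_r1	Ler	Col-0	WT	WT	two_four_cell	1	x1	embryo	run1
LxC_24_r2	Ler	Col-0	WT	WT	two_four_cell	2	x1	embryo	run1
CxL_gl_r1	Col-0	Ler	WT	WT	globular	1	x1	embryo	run1
CxL_gl_r2	Col-0	Ler	WT	WT	globular	2	x1	embryo	run1
LxC_gl_r1	Ler	Col-0	WT	WT	globular	1	x1	embryo	run1
LxC_gl_r2	Ler	Col-0	WT	WT	globular	2	x1	embryo	run1
CxL_24_6x	Col-0	Ler	WT	WT	two_four_cell	1	x6	embryo	run1
LxC_24_6x	Ler	Col-0	WT	WT	two_four_cell	1	x6	embryo	run1
fieCxL_24	Col-0	Ler	fie_het	WT	two_four_cell	1	x1	embryo	run1
fieCxL_gl	Col-0	Ler	fie_het	WT	globular	1	x1	embryo	run1
LxfieC_24	Ler	Col-0	WT	fie_het	two_four_cell	1	x1	embryo	run1
LxmetC_24	Ler	Col-0	WT	met1_het	two_four_cell	1	x1	embryo	run1
CxL_sdl	Col-0	Ler	WT	WT	seedling	1	n/a	seedling	run1
LxC_sdl	Ler	Col-0	WT	WT	seedling	1	n/a	seedling	run1
SCE	Col-0	Ler	WT	WT	endosperm	1	n/a	seedcoat_endosperm	run1
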