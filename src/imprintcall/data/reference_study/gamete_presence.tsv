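gene_id	egg_present	sperm_present
AT1G29660	0	0
AT1G72260	1	0
AT5G62210	0	0
AT3G20520	0	0
AT2G17710	0	0
AT3G21500	0	0
AT2G01520	0	0
AT1G20680	0	0
AT5G51950	0	0
AT1G29050	0	0
AT3G26790	0	0
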