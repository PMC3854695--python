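gene_id	candidate_class
AT1G29660	MEG
AT1G72260	MEG
AT2G47115	MEG
AT5G62210	MEG
AT3G20520	MEG
AT2G17710	MEG
AT3G21500	MEG
AT2G01520	MEG
AT1G20680	MEG
AT5G51950	MEG
AT1G29050	MEG
AT3G44260	MEG
AT5G52060	MEG
AT4G11960	MEG
MEGC13	MEG
MEGC14	MEG
MEGC15	MEG
MEGC16	MEG
AT3G26790	PEG
AT2G20160	PEG
AT1G63260	PEG
PEGC04	PEG
PEGC05	PEG
PEGC06	PEG
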