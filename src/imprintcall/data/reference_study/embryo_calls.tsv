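gene_id	sample_id	call
AT1G29660	CxL_24_r1	maternal_only
AT1G29660	CxL_24_r2	maternal_only
AT1G29660	LxC_24_r1	maternal_only
AT1G29660	LxC_24_r2	maternal_only
AT1G29660	CxL_gl_r1	maternal_only
AT1G29660	CxL_gl_r2	maternal_only
AT1G29660	LxC_gl_r1	maternal_only
AT1G29660	LxC_gl_r2	maternal_only
AT1G72260	CxL_24_r1	maternal_only
AT1G72260	CxL_24_r2	maternal_only
AT1G72260	LxC_24_r1	maternal_only
AT1G72260	LxC_24_r2	maternal_only
AT1G72260	CxL_gl_r1	maternal_only
AT1G72260	CxL_gl_r2	maternal_only
AT1G72260	LxC_gl_r1	maternal_only
AT1G72260	LxC_gl_r2	maternal_only
AT2G47115	CxL_24_r1	maternal_only
AT2G47115	CxL_24_r2	maternal_only
AT2G47115	LxC_24_r1	maternal_only
AT2G47115	LxC_24_r2	maternal_only
AT2G47115	CxL_gl_r1	maternal_only
AT2G47115	CxL_gl_r2	maternal_only
AT2G47115	LxC_gl_r1	maternal_only
AT2G47115	LxC_gl_r2	maternal_only
AT5G62210	CxL_24_r1	maternal_only
AT5G62210	CxL_24_r2	maternal_only
AT5G62210	LxC_24_r1	maternal_only
AT5G62210	LxC_24_r2	maternal_only
AT5G62210	CxL_gl_r1	maternal_only
AT5G62210	CxL_gl_r2	maternal_only
AT5G62210	LxC_gl_r1	maternal_only
AT5G62210	LxC_gl_r2	maternal_only
AT3G20520	CxL_24_r1	maternal_only
AT3G20520	CxL_24_r2	maternal_only
AT3G20520	LxC_24_r1	maternal_only
AT3G20520	LxC_24_r2	maternal_only
AT3G20520	CxL_gl_r1	maternal_only
AT3G20520	CxL_gl_r2	maternal_only
AT3G20520	LxC_gl_r1	maternal_only
AT3G20520	LxC_gl_r2	maternal_only
AT2G17710	CxL_24_r1	maternal_only
AT2G17710	CxL_24_r2	maternal_only
AT2G17710	LxC_24_r1	maternal_only
AT2G17710	LxC_24_r2	maternal_only
AT2G17710	CxL_gl_r1	maternal_only
AT2G17710	CxL_gl_r2	maternal_only
AT2G17710	LxC_gl_r1	maternal_only
AT2G17710	LxC_gl_r2	maternal_only
AT3G21500	CxL_24_r1	maternal_only
AT3G21500	CxL_24_r2	maternal_only
AT3G21500	LxC_24_r1	maternal_only
AT3G21500	LxC_24_r2	maternal_only
AT3G21500	CxL_gl_r1	maternal_only
AT3G21500	CxL_gl_r2	maternal_only
AT3G21500	LxC_gl_r1	maternal_only
AT3G21500	LxC_gl_r2	maternal_only
AT2G01520	CxL_24_r1	maternal_only
AT2G01520	CxL_24_r2	maternal_only
AT2G01520	LxC_24_r1	maternal_only
AT2G01520	LxC_24_r2	maternal_only
AT2G01520	CxL_gl_r1	maternal_only
AT2G01520	CxL_gl_r2	maternal_only
AT2G01520	LxC_gl_r1	maternal_only
AT2G01520	LxC_gl_r2	maternal_only
AT1G20680	CxL_24_r1	maternal_only
AT1G20680	CxL_24_r2	maternal_only
AT1G20680	LxC_24_r1	maternal_only
AT1G20680	LxC_24_r2	maternal_only
AT1G20680	CxL_gl_r1	maternal_only
AT1G20680	CxL_gl_r2	maternal_only
AT1G20680	LxC_gl_r1	maternal_only
AT1G20680	LxC_gl_r2	not_detected
AT5G51950	CxL_24_r1	maternal_only
AT5G51950	CxL_24_r2	maternal_only
AT5G51950	LxC_24_r1	maternal_only
AT5G51950	LxC_24_r2	maternal_only
AT5G51950	CxL_gl_r1	maternal_only
AT5G51950	CxL_gl_r2	maternal_only
AT5G51950	LxC_gl_r1	maternal_only
AT5G51950	LxC_gl_r2	maternal_only
AT1G29050	CxL_24_r1	maternal_only
AT1G29050	CxL_24_r2	maternal_only
AT1G29050	LxC_24_r1	maternal_only
AT1G29050	LxC_24_r2	maternal_only
AT1G29050	CxL_gl_r1	maternal_only
AT1G29050	CxL_gl_r2	not_detected
AT1G29050	LxC_gl_r1	maternal_only
AT1G29050	LxC_gl_r2	maternal_only
AT3G44260	CxL_24_r1	biallelic
AT3G44260	CxL_24_r2	maternal_only
AT3G44260	LxC_24_r1	maternal_only
AT3G44260	LxC_24_r2	maternal_only
AT3G44260	CxL_gl_r1	maternal_only
AT3G44260	CxL_gl_r2	maternal_only
AT3G44260	LxC_gl_r1	maternal_only
AT3G44260	LxC_gl_r2	maternal_only
AT5G52060	CxL_24_r1	biallelic
AT5G52060	CxL_24_r2	maternal_only
AT5G52060	LxC_24_r1	maternal_only
AT5G52060	LxC_24_r2	maternal_only
AT5G52060	CxL_gl_r1	maternal_only
AT5G52060	CxL_gl_r2	maternal_only
AT5G52060	LxC_gl_r1	maternal_only
AT5G52060	LxC_gl_r2	maternal_only
AT4G11960	CxL_24_r1	maternal_only
AT4G11960	CxL_24_r2	maternal_only
AT4G11960	LxC_24_r1	maternal_only
AT4G11960	LxC_24_r2	maternal_only
AT4G11960	CxL_gl_r1	maternal_only
AT4G11960	CxL_gl_r2	maternal_only
AT4G11960	LxC_gl_r1	maternal_only
AT4G11960	LxC_gl_r2	maternal_only
MEGC13	CxL_24_r1	not_detected
MEGC13	CxL_24_r2	not_detected
MEGC13	LxC_24_r1	not_detected
MEGC13	LxC_24_r2	not_detected
MEGC13	CxL_gl_r1	not_detected
MEGC13	CxL_gl_r2	not_detected
MEGC13	LxC_gl_r1	not_detected
MEGC13	LxC_gl_r2	not_detected
MEGC14	CxL_24_r1	not_detected
MEGC14	CxL_24_r2	not_detected
MEGC14	LxC_24_r1	not_detected
MEGC14	LxC_24_r2	not_detected
MEGC14	CxL_gl_r1	not_detected
MEGC14	CxL_gl_r2	not_detected
MEGC14	LxC_gl_r1	not_detected
MEGC14	LxC_gl_r2	not_detected
MEGC15	CxL_24_r1	not_detected
MEGC15	CxL_24_r2	not_detected
MEGC15	LxC_24_r1	not_detected
MEGC15	LxC_24_r2	not_detected
MEGC15	CxL_gl_r1	not_detected
MEGC15	CxL_gl_r2	not_detected
MEGC15	LxC_gl_r1	not_detected
MEGC15	LxC_gl_r2	not_detected
MEGC16	CxL_24_r1	not_detected
MEGC16	CxL_24_r2	not_detected
MEGC16	LxC_24_r1	not_detected
MEGC16	LxC_24_r2	not_detected
MEGC16	CxL_gl_r1	not_detected
MEGC16	CxL_gl_r2	not_detected
MEGC16	LxC_gl_r1	not_detected
MEGC16	LxC_gl_r2	not_detected
AT3G26790	CxL_24_r1	paternal_only
AT3G26790	CxL_24_r2	paternal_only
AT3G26790	LxC_24_r1	paternal_only
AT3G26790	LxC_24_r2	paternal_only
AT3G26790	CxL_gl_r1	maternal_only
AT3G26790	CxL_gl_r2	not_detected
AT3G26790	LxC_gl_r1	biallelic
AT3G26790	LxC_gl_r2	not_detected
AT2G20160	CxL_24_r1	biallelic
AT2G20160	CxL_24_r2	biallelic
AT2G20160	LxC_24_r1	biallelic
AT2G20160	LxC_24_r2	not_detected
AT2G20160	CxL_gl_r1	biallelic
AT2G20160	CxL_gl_r2	not_detected
AT2G20160	LxC_gl_r1	biallelic
AT2G20160	LxC_gl_r2	not_detected
AT1G63260	CxL_24_r1	biallelic
AT1G63260	CxL_24_r2	biallelic
AT1G63260	LxC_24_r1	biallelic
AT1G63260	LxC_24_r2	not_detected
AT1G63260	CxL_gl_r1	biallelic
AT1G63260	CxL_gl_r2	not_detected
AT1G63260	LxC_gl_r1	biallelic
AT1G63260	LxC_gl_r2	biallelic
PEGC04	CxL_24_r1	not_detected
PEGC04	CxL_24_r2	not_detected
PEGC04	LxC_24_r1	not_detected
PEGC04	LxC_24_r2	not_detected
PEGC04	CxL_gl_r1	not_detected
PEGC04	CxL_gl_r2	not_detected
PEGC04	LxC_gl_r1	not_detected
PEGC04	LxC_gl_r2	not_detected
PEGC05	CxL_24_r1	not_detected
PEGC05	CxL_24_r2	not_detected
PEGC05	LxC_24_r1	not_detected
PEGC05	LxC_24_r2	not_detected
PEGC05	CxL_gl_r1	not_detected
PEGC05	CxL_gl_r2	not_detected
PEGC05	LxC_gl_r1	not_detected
PEGC05	LxC_gl_r2	not_detected
PEGC06	CxL_24_r1	not_detected
PEGC06	CxL_24_r2	not_detected
PEGC06	LxC_24_r1	not_detected
PEGC06	LxC_24_r2	not_detected
PEGC06	CxL_gl_r1	not_detected
PEGC06	CxL_gl_r2	not_detected
PEGC06	LxC_gl_r1	not_detected
PEGC06	LxC_gl_r2	not_detected
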