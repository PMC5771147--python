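gene	rsid	chrom	pos	derived	group
ACKR1	rs2814778	1	159174683	C	AFR
SLC39A4	rs1871534	8	145639681	G	AFR
ABCC11	rs17822931	16	48258198	A	EAS
EDAR	rs3827760	2	109513601	G	EAS
HERC2	rs12913832	15	28365618	G	EUR
MCM6	rs4988235	2	136608646	A	EUR
SLC24A5	rs1426654	15	48426484	A	EUR
SLC45A2	rs16891982	5	33951693	G	EUR
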