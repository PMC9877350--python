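# Per-variant in-silico annotations for the 28 CYP2C19 variants selected for
# the enzyme-activity assay (24 novel + 4 star-allele-defining). Scores are the
# published SIFT / PolyPhen-2 / CADD (phred) values and 1000 Genomes allele
# frequencies; genomic coordinates are SYNTHETIC placeholders (linear map
# pos = 96522462 + cDNA position, GRCh37 region chr10:96522438-96615304).
# in_table = 1 marks variants present in the star-allele definition table.
chrom	pos	ref	alt	cdna	rsid	consequence	sift	polyphen2	cadd	af	acmg	in_table
10	96522586	A	G	NM_000769.4:c.124A>G	rs559087813	missense	0.33	0.00	6.33	0.0002	VUS	0
10	96522626	C	G	NM_000769.4:c.164C>G	rs572853437	missense	0.85	0.00	0.00	0.0008	VUS	0
10	96522680	G	A	NM_000769.4:c.218G>A	rs201306972	missense	0.01	0.02	8.90	0.0006	VUS	0
10	96522683	T	C	NM_000769.4:c.221T>C	rs28399505	missense	0.70	0.00	0.03	0.0008	VUS	0
10	96522788	G	C	NM_000769.4:c.326G>C	rs200347843	missense	0.01	0.05	12.76	0.0004	VUS	0
10	96522835	C	T	NM_000769.4:c.373C>T	rs200150287	missense	0.01	0.99	23.70	0.0002	VUS	0
10	96522851	C	T	NM_000769.4:c.389C>T	rs150152656	missense	0.00	1.00	22.10	0.0002	VUS	0
10	96522856	C	T	NM_000769.4:c.394C>T	rs149590953	missense	0.00	0.99	21.90	0.0006	VUS	0
10	96522940	A	G	NM_000769.4:c.478A>G	rs375760063	missense	0.21	0.02	15.59	0.0002	VUS	0
10	96523018	C	T	NM_000769.4:c.556C>T	rs183701923	missense	0.02	1.00	24.80	0.0004	VUS	0
10	96523055	T	C	NM_000769.4:c.593T>C	rs186489608	missense	0.01	0.26	19.68	0.0002	VUS	0
10	96523200	G	T	NM_000769.4:c.738G>T	rs574458036	missense	0.09	0.00	4.46	0.0002	VUS	0
10	96523240	C	A	NM_000769.4:c.778C>A	rs556994963	missense	0.00	1.00	23.90	0.0002	VUS	0
10	96523246	G	A	NM_000769.4:c.784G>A	rs577255883	missense	0.06	0.68	24.90	0.0006	VUS	0
10	96523293	C	A	NM_000769.4:c.831C>A	rs559628884	missense	0.06	0.29	4.11	0.0002	VUS	0
10	96523299	G	T	NM_000769.4:c.837G>T	rs547822797	missense	0.44	0.00	8.78	0.0002	VUS	0
10	96523447	C	T	NM_000769.4:c.985C>T	rs59734894	missense	0.06	0.49	13.32	0.0002	VUS	0
10	96523465	C	T	NM_000769.4:c.1003C>T	rs368758960	missense	0.00	1.00	23.10	0.0002	VUS	0
10	96523496	T	A	NM_000769.4:c.1034T>A	rs201132803	missense	0.00	1.00	25.20	0.0002	VUS	0
10	96523612	G	C	NM_000769.4:c.1150G>C	rs188851578	missense	0.01	1.00	26.50	0.0002	VUS	0
10	96523622	T	C	NM_000769.4:c.1160T>C	rs562912432	missense	0.00	1.00	22.20	0.0002	VUS	0
10	96523757	A	T	NM_000769.4:c.1295A>T	rs146991374	missense	0.00	1.00	23.00	0.0010	VUS	0
10	96523792	G	C	NM_000769.4:c.1330G>C	rs540369401	missense	0.00	1.00	26.20	0.0002	VUS	0
10	96523927	C	T	NM_000769.4:c.1465C>T	rs542090374	missense	0.00	0.98	19.28	0.0002	VUS	0
10	96522893	G	A	NM_000769.4:c.431G>A	rs17884712	missense	0.01	1.00	23.70	0.0028	VUS	1
10	96523098	G	A	NM_000769.4:c.636G>A	rs4986893	stop_gained	NA	NA	34.00	0.0142	VUS	1
10	96523453	G	A	NM_000769.4:c.991G>A	rs3758581	missense	1.00	0.01	0.00	0.0485	VUS	1
10	96523690	C	T	NM_000769.4:c.1228C>T	rs17879685	missense	0.01	0.00	16.96	0.0056	LB	1
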