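# CYP2C19 core star-allele definition table (PharmVar-style, core alleles only).
# Genomic coordinates are SYNTHETIC placeholders inside the configured gene
# region chr10:96522438-96615304 (GRCh37): coding variants use the linear map
# pos = 96522462 + cDNA position; the non-coding definers of *17/*27/*35 use
# hand-picked in-region positions. cDNA labels and rsIDs are authentic.
# Cell values: 1 = defining variant present on the allele, 0 = reference base.
allele	function	10:96522463:A:G|NM_000769.4:c.1A>G|rs28399504	10:96522893:G:A|NM_000769.4:c.431G>A|rs17884712	10:96523098:G:A|NM_000769.4:c.636G>A|rs4986893	10:96523143:G:A|NM_000769.4:c.681G>A|rs4244285	10:96523453:G:A|NM_000769.4:c.991G>A|rs3758581	10:96523690:C:T|NM_000769.4:c.1228C>T|rs17879685	10:96610000:C:T|synthetic:*17-marker	10:96611000:G:A|synthetic:*27-marker	10:96612000:A:G|synthetic:*35-marker
*1	normal	0	0	0	0	0	0	0	0	0
*2	no_function	0	0	0	1	0	0	0	0	0
*3	no_function	0	0	1	0	0	0	0	0	0
*4	no_function	1	0	0	0	0	0	0	0	0
*9	decreased	0	1	0	0	0	0	0	0	0
*13	normal	0	0	0	0	0	1	0	0	0
*17	increased	0	0	0	0	0	0	1	0	0
*27	uncertain	0	0	0	0	0	0	0	1	0
*35	no_function	0	0	0	0	0	0	0	0	1
*38	normal	0	0	0	0	1	0	0	0	0
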