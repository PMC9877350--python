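# Functional-assay summary per recombinant CYP2C19 preparation: immunoblot
# expression flag, specific P450 content from the CO-difference spectrum
# (pmol/mg protein), metabolite-formation rates (mean +/- SD of triplicates,
# pmol/min/pmol P450) for S-mephenytoin and omeprazole, and the published %WT
# values (derived from unrounded means). ND = not detected; NA = not applicable.
# novel = 1 marks variants absent from the star-allele definition table.
variant	star_allele	expression_detected	specific_content	meph_mean	meph_sd	omep_mean	omep_sd	n	pct_wt_meph	pct_wt_omep	novel
NM_000769.4:c.124A>G	NA	1	96.7	0.24	0.03	4.41	0.31	3	103.9	104.2	1
NM_000769.4:c.164C>G	NA	1	71.6	0.36	0.06	5.11	0.37	3	155.6	120.7	1
NM_000769.4:c.218G>A	NA	1	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.221T>C	NA	1	429.3	0.28	0.03	2.88	0.07	3	119.1	67.9	1
NM_000769.4:c.326G>C	NA	1	25.0	0.21	0.00	6.44	0.43	3	90.1	152.2	1
NM_000769.4:c.373C>T	NA	1	128.6	ND	ND	0.96	0.10	3	NA	22.6	1
NM_000769.4:c.389C>T	NA	1	46.0	0.04	0.01	3.67	0.08	3	15.5	86.8	1
NM_000769.4:c.394C>T	NA	1	190.1	ND	ND	0.48	0.04	3	NA	11.3	1
NM_000769.4:c.431G>A	*9	1	163.2	0.07	0.00	2.67	0.22	3	31.8	63.1	0
NM_000769.4:c.478A>G	NA	1	206.8	0.22	0.01	4.41	0.13	3	94.0	104.1	1
NM_000769.4:c.556C>T	NA	0	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.593T>C	NA	1	51.5	0.12	0.01	3.44	0.25	3	49.6	81.2	1
NM_000769.4:c.636G>A	*3	0	ND	ND	ND	ND	ND	3	NA	NA	0
NM_000769.4:c.738G>T	NA	1	140.5	0.23	0.03	4.11	0.05	3	97.8	97.0	1
NM_000769.4:c.778C>A	NA	0	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.784G>A	NA	0	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.831C>A	NA	1	123.2	0.30	0.04	4.81	0.39	3	126.8	113.7	1
NM_000769.4:c.837G>T	NA	1	211.3	0.29	0.05	4.48	0.05	3	122.8	105.8	1
NM_000769.4:c.985C>T	NA	1	96.5	0.39	0.05	4.88	0.22	3	165.2	115.4	1
NM_000769.4:c.991G>A	*38	1	167.0	0.09	0.01	2.96	0.09	3	37.8	70.0	0
NM_000769.4:c.1003C>T	NA	0	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.1034T>A	NA	0	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.1150G>C	NA	0	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.1160T>C	NA	0	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.1228C>T	*13	1	195.6	0.23	0.03	4.13	0.25	3	100.1	97.5	0
NM_000769.4:c.1295A>T	NA	0	ND	ND	ND	ND	ND	3	NA	NA	1
NM_000769.4:c.1330G>C	NA	1	299.1	0.04	0.002	1.77	0.05	3	15.9	41.9	1
NM_000769.4:c.1465C>T	NA	1	26.3	0.41	0.07	11.38	0.53	3	174.7	269.0	1
WT	*1	1	208.2	0.23	0.004	4.23	0.05	3	100.0	100.0	0
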