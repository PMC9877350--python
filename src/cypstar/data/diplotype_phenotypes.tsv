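# CYP2C19 diplotype -> metabolizer phenotype map with cohort counts
# (1000 Genomes phase III, 2,504 subjects; PharmGKB-style translation).
# "unk" denotes a haplotype matching no defined star allele.
phenotype	count	diplotypes
UM	73	*17|*17
RM	412	*1|*17,*13|*17
NM	810	*1|*1,*1|*13
IM	814	*1|*3,*1|*4,*2|*1,*2|*13,*2|*17,*3|*17,*35|*1,*35|*13,*35|*17
PM	178	*2|*2,*2|*3,*2|*35,*3|*3,*35|*35
PossibleIM	11	*1|*9,*9|*13,*9|*17
PossiblePM	1	*2|*9
Indeterminate	99	*1|*27,*2|*27,*9|*27,*13|*27,*27|*17,*27|*27,*35|*27
Unknown	106	*1|unk,*2|unk,*9|unk,*13|unk,*17|unk,*27|unk,*35|unk,unk|*1,unk|*13,unk|*17,unk|*27,unk|*3,unk|unk
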