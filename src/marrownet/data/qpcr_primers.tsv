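gene	direction	sequence	product_size_bp
Ccl3	sense	CAAGTCTTCTCAGCGCCAT	158
Ccl3	antisense	ATCTGCCGGTTTCTCTTAGTCA	158
Ctsk	sense	GGGCCAGGATGAAAGTTGTA	106
Ctsk	antisense	CACTGCTCTCTTCAGGGCTT	106
Cxcl12	sense	ACATCGCCAGAGCCAACGTCA	111
Cxcl12	antisense	TCGGGTCAATGCACACTTGTCT	111
Pten	sense	ACTGCACGAATAATAAGGCAT	152
Pten	antisense	TAAAATTGAAGCCCTAATCCC	152
Adipoq	sense	CACTGGCAAGTTCTACTGCAA	140
Adipoq	antisense	TCTTTTCCTGATACTGGTCGT	140
Tob1	sense	TGCTCTTTCTCCCAATGCCAA	149
Tob1	antisense	CTCCGTAGGCCGCAAACAC	149
Gapdh	sense	TGTGTCCGTCGTGGATCTGA	104
Gapdh	antisense	TTGCTGTTGAAGTCGCAGGAG	104
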