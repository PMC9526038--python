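# Worked-example gene: a hypothetical gene with P_N=11 (7 below 15% DAF),
# P_S=17 (6 below 15%), D_N=15, D_S=8 at n=20 sampled haploids.
# The per-class placement within each frequency band is a synthetic
# reconstruction; every band total and test statistic is determined by the
# quantities above.
gene_id	n	folded	sfs_n	sfs_s	dn	ds	mn	ms
example	20	0	4,3,2,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0	4,2,3,3,2,2,1,0,0,0,0,0,0,0,0,0,0,0,0	15	8	500	200
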