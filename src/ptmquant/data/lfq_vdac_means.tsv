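protein	cell_line	mean_lfq_intensity	sd_percent	published_share
VDAC1	NSC34	1.10e9	1	66.71
VDAC2	NSC34	2.40e8	4	14.55
VDAC3	NSC34	3.09e8	15	18.74
VDAC1	NSC34-SOD1WT	1.19e9	27	65.67
VDAC2	NSC34-SOD1WT	2.46e8	20	13.59
VDAC3	NSC34-SOD1WT	3.75e8	16	20.74
VDAC1	NSC34-SOD1G93A	1.10e9	7	64.08
VDAC2	NSC34-SOD1G93A	3.51e8	11	20.43
VDAC3	NSC34-SOD1G93A	2.66e8	13	15.50
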