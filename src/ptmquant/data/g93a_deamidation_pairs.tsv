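sequence	start	end	site_residue	site_pos	charge_deam	mz_deam	intensity_deam	charge_norm	mz_norm	intensity_norm	published_ratio
TKSENGLEFTSSGSANTETTK	33	53	N	37	3	730.6730	6.3e6	3	730.3450	3.3e8	0.02
SENGLEFTSSGSANTETTK	35	53	N	37	3	654.2921	6.3e5	2	980.4425	1.4e8	0.01
LTFDSSFSPNTGKK	97	110	N	106	3	510.5876	1.3e6	2	764.8857	9.9e7	0.01
VTQSNFAVGYK	164	174	Q	166	2	607.8062	1.4e6	2	607.3142	6.2e8	0.002
KLETAVNLAWTAGNSNTR	201	218	N	207	3	649.6692	9.6e6	3	649.3412	1.6e7	0.6
LETAVNLAWTAGNSNTR	202	218	N	214	2	909.9527	6.8e5	2	909.4607	1.9e7	0.04
YQVDPDACFSAK	225	236	Q	226	2	701.3032	1.6e6	2	700.8112	7.1e8	0.002
VNNSSLIGLGYTQTLKPGIK	237	256	N	239	3	702.0598	2.4e6	3	701.7318	7.4e7	0.03
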