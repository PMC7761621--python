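group	replicate	sequence	start	end	site_residue	site_pos	modification	charge_mod	mz_mod	intensity_mod	charge_ref	mz_ref	intensity_ref
cys127_trioxidation	I	EHINLGCDVDFDIAGPSIR	121	139	C	127	trioxidation	2	1059.9921	8.2e5	3	710.0155	2.8e4
cys127_trioxidation	II	EHINLGCDVDFDIAGPSIR	121	139	C	127	trioxidation	2	1059.9915	6.9e5	3	710.0140	3.6e4
cys127_trioxidation	III	EHINLGCDVDFDIAGPSIR	121	139	C	127	trioxidation	2	1059.9928	7.8e5	3	710.0140	3.3e4
met155_sulfoxide	I	GALVLGYEGWLAGYQMNFETSK	140	161	M	155	oxidation	2	1225.5892	4.5e6	2	1217.5931	7.5e4
met155_sulfoxide	II	GALVLGYEGWLAGYQMNFETSK	140	161	M	155	oxidation	2	1225.5897	4.9e6	2	1217.5913	6.9e4
met155_sulfoxide	III	GALVLGYEGWLAGYQMNFETSK	140	161	M	155	oxidation	3	817.3946	2.8e6	3	812.0656	5.4e4
met155_sulfone	I	GALVLGYEGWLAGYQMNFETSK	140	161	M	155	dioxidation	3	822.7261	2.2e5	2	1217.5931	7.5e4
met155_sulfone	II	GALVLGYEGWLAGYQMNFETSK	140	161	M	155	dioxidation	3	822.7269	4.5e5	2	1217.5913	6.9e4
met155_sulfone	III	GALVLGYEGWLAGYQMNFETSK	140	161	M	155	dioxidation	3	822.7277	2.6e5	3	812.0656	5.4e4
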