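hgvs_p	consequence	revel_call	cadd_call	ada_score	rf_score	hgmd_label	clinvar_label	n_patient_carriers	n_hc_carriers	min_carrier_aao	secondary_structure
p.K13R	missense	T	T					2	2	60
p.Y61H	missense	D	D					1	0	38	helix
p.R78C	missense	T	D			PD susceptibility		2	0	60
p.A97G	missense	T	T					1	0	60	coil
p.L213P	missense	D	D					1	0	60	helix
p.A215D	missense	D	D					1	0	60	helix
p.T408T	splice_region			0.9797	0.85	DM		2	1	60
p.E427K	missense	T	D			reduced activity	parkinsonism	1	1	60
p.R434C	missense	D	D					1	0	60
p.A495P	missense	T	D					1	2	60
p.H529R	missense	T	T					1	0	60
p.R534C	missense	T	T					1	0	60
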