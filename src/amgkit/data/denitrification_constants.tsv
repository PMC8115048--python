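species	formula	charge	phase	dGf_kJ_per_mol	dGf_reference_kJ_per_mol	note
nitrate	NO3	-1	aq	-118.06	-111.3	effective value; calibrated (see docs/methods.md)
nitrite	NO2	-1	aq	-20.49	-37.2	effective value; calibrated (see docs/methods.md)
nitric_oxide	NO	0	aq	67.43	102.06	effective value; calibrated (see docs/methods.md)
nitrous_oxide	N2O	0	gas	85.43	104.2	effective value; calibrated (see docs/methods.md)
dinitrogen	N2	0	gas	0.0	0.0	element reference state
pyruvate	C3H3O3	-1	aq	-474.63	-474.63	Thauer et al. 1977
co2	CO2	0	gas	-394.36	-394.36	Thauer et al. 1977
water	H2O	0	liquid	-237.18	-237.18	Thauer et al. 1977
proton	H	1	aq	-39.96	-39.96	transformed value at pH 7, 25 C (-RT ln 10^-7)
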