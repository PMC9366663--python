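bcu_id	vendor_code	pulse_peak_b_ut	fwhm_ms	dbdt_peak_ts	b_iec_pulse_ut	ein_peak_vm	estimate_kind	substituted_from	share_pct
I	A	406	1.95	0.31	287	0.038	calculated		41.6
II	A					0.038	substituted	I	0.7
III	A					0.038	substituted	I	1.7
IV	A					0.038	substituted	I	2.7
V	A	338	2.45	0.81	239	0.054	calculated		27.0
VI	B					0.038	substituted	I	2.4
VII	B					0.038	substituted	I	0.3
VIII	C	60	0.9	0.16	42	0.015	rough_estimate		10.8
IX	unknown					0.038	substituted	I	12.8
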