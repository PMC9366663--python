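gate_id	vendor_code	frequency_hz	b_iec_ut	share_pct	substituted_from
I	A	220	87	38.0	
II	A	14000	111	11.5	
III	A	220	87	0.5	I
IV	B	366	87	15.9	
V	B	366	68	8.2	
VI	B	366	87	1.9	IV
VII	C	220	106	1.4	
VIII	unknown	220	87	22.6	I
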