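trait	mqtl_id	chromosome	position_Mb
Zn	MQTL-3/Chr3	3	5.325
Zn	MQTL-5/Chr3	3	12.43
Fe	MQTL-3/Chr3	3	5.290
Fe	MQTL-3/Chr3	3	5.300
Fe	MQTL-5/Chr3	3	14.59
Mn	MQTL-4/Chr3	3	8.478
Mn	MQTL-4/Chr3	3	8.479
Mn	MQTL-3/Chr4	4	6.473
Mn	MQTL-3/Chr4	4	6.553
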