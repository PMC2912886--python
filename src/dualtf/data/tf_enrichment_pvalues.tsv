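# Externally computed TFBS enrichment p-values for CRM sets split by the
# preferred role (activator vs repressor) of Hb and of Kr. Blank cells mean
# the TF/set pair was not tested.
id	comparison	p_act	p_rep
Abd-B	Hb	0.0	0.0
Abd-B	Kr	0.0	0.0
Deaf1	Hb		
Deaf1	Kr	0.079	0.005
His2B	Hb	0.048	0.0
His2B	Kr	0.0	0.058
Hsf	Hb	0.085	0.008
Hsf	Kr	0.0	0.231
Kr	Hb	0.0	0.0
Kr	Kr	0.0	0.0
Bcd	Hb	0.0	0.0
Bcd	Kr	0.0	0.0
Br-Z4	Hb		
Br-Z4	Kr	0.821	0.006
Cad	Hb	0.002	0.0
Cad	Kr	0.0	0.0
Hb	Hb	0.032	0.0
Hb	Kr	0.0	0.0
Kni	Hb	0.032	0.01
Kni	Kr	0.702	0.0
Tll	Hb	0.003	0.0
Tll	Kr	0.0	0.0
Ttk	Hb	0.02	0.0
Ttk	Kr	0.003	0.0
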