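species	abbreviation	group	neutral	acid	lipase2	lipase3	GDSL	HSL	total
Apocrypta bakeri	Abak	NPFW	29	15	0	2	2	1	49
Philotrypesis tridentata	Ptri	NPFW	32	30	0	1	1	1	65
Sycobia sp.2	Sbsp	NPFW	29	17	0	2	1	1	50
Sycophila sp.2	Spsp	NPFW	26	30	0	1	2	1	60
Sycophaga agraensis	Sagr	NPFW	26	12	0	1	0	1	40
Dolichoris vasculosae	Dvas	PFW	18	12	0	1	1	1	33
Wiebesia pumilae	Wpum	PFW	18	10	0	1	1	1	31
Ceratosolen solmsi	Csol	PFW	17	11	0	1	1	1	31
Ceratosolen fusciceps	Cfus	PFW	15	11	0	1	1	1	29
Eupristina koningsbergeri	Ekon	PFW	15	11	0	2	1	2	31
Platyscapa corneri	Pcor	PFW	19	11	0	1	1	1	33
Kradibia gibbosae	Kgib	PFW	15	12	0	1	0	1	29
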