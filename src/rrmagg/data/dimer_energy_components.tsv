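model	dE_ele	dE_vdw	dE_int	dG_np_solv	dG_pb_solv	TdS	dG_np	dG_pb	dH_binding	dG_binding
SaSb/D	-574.68	-147.57	0.00	-19.14	633.36	-50.36	-166.71	58.69	-108.02	-57.66
SbSb/D	-160.57	-146.63	0.00	-18.15	231.30	-52.08	-164.78	70.73	-94.05	-41.97
SbH1a1/D	-307.64	-155.24	0.00	-19.26	397.46	-61.57	378.20	-174.50	-79.86	-23.11
SbH1a2/D	-252.14	-74.73	0.00	-10.29	279.29	-33.23	269.00	-85.02	-57.87	-17.80
H1H1/D	-188.48	-58.48	0.00	-7.05	209.91	-39.88	202.86	-65.53	-44.10	-4.22
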