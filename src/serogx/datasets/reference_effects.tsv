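analyte	group	beta	se	p_label
TOXO	SZ	-0.02	0.20	n/a
TOXO	SZ_mother	0.30	0.23	0.095
TOXO	SZ_father	0.09	0.25	n.s.
TOXO	BP	0.04	0.21	n.s.
TOXO	BP_mother	0.10	0.23	n.s.
TOXO	BP_father	0.04	0.25	n.s.
HSV1	SZ	-0.20	0.16	n/a
HSV1	SZ_mother	0.23	0.19	n.s.
HSV1	SZ_father	0.43	0.22	0.027
HSV1	BP	0.24	0.16	0.07
HSV1	BP_mother	0.48	0.18	0.005
HSV1	BP_father	0.41	0.21	0.026
CMV	SZ	-0.01	0.17	n/a
CMV	SZ_mother	0.19	0.20	n.s.
CMV	SZ_father	0.65	0.23	0.002
CMV	BP	0.26	0.17	0.06
CMV	BP_mother	0.19	0.19	0.06
CMV	BP_father	0.48	0.22	0.015
HHV6	SZ	0.12	0.09	0.07
HHV6	SZ_mother	0.17	0.11	0.07
HHV6	SZ_father	0.20	0.14	0.07
HHV6	BP	0.19	0.09	0.026
HHV6	BP_mother	0.06	0.11	n.s.
HHV6	BP_father	0.12	0.14	n.s.
GLIADIN	SZ	0.07	0.08	n.s.
GLIADIN	SZ_mother	-0.10	0.10	n/a
GLIADIN	SZ_father	0.02	0.12	n.s.
GLIADIN	BP	0.04	0.08	n.s.
GLIADIN	BP_mother	0.07	0.10	n.s.
GLIADIN	BP_father	0.04	0.11	n.s.
CRP	SZ	1.04	0.12	1.2E-16
CRP	SZ_mother	0.25	0.16	0.06
CRP	SZ_father	0.05	0.17	n.s.
CRP	BP	0.42	0.14	0.0013
CRP	BP_mother	0.44	0.15	0.002
CRP	BP_father	0.20	0.16	n.s.
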