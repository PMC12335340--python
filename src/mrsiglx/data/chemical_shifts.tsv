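# Proton chemical shifts for the shipped metabolite spin systems.
# Columns: metabolite, proton label, shift (ppm), equivalence group, subsystem id.
# Protons sharing a subsystem id are scalar-coupled (or potentially so); protons
# in different subsystems evolve independently. Uncoupled singlet protons
# (N-trimethyl, acetyl CH3, glycine CH2) are listed as one-spin subsystems.
# GPC is modelled by its choline moiety (trimethyl + two CH2 groups); the
# glycerol backbone resonances lie under water and are omitted.
# Glc is modelled as the beta anomer.
metabolite	proton	shift_ppm	group	subsystem
NAA	ace1	2.0080	ace	1
NAA	ace2	2.0080	ace	2
NAA	ace3	2.0080	ace	3
NAA	H2	4.3817	H2	4
NAA	H3	2.6727	H3	4
NAA	H3p	2.4863	H3p	4
NAAG	ace1	2.0420	ace	1
NAAG	ace2	2.0420	ace	2
NAAG	ace3	2.0420	ace	3
NAAG	H2	4.6070	H2	4
NAAG	H3	2.7210	H3	4
NAAG	H3p	2.5190	H3p	4
NAAG	H2g	4.1280	H2g	5
NAAG	H3g	2.0490	H3g	5
NAAG	H3gp	1.8810	H3gp	5
NAAG	H4g	2.1900	H4g	5
NAAG	H4gp	2.1800	H4gp	5
Cho	Me1	3.1850	NMe3	1
Cho	Me2	3.1850	NMe3	2
Cho	Me3	3.1850	NMe3	3
Cho	Me4	3.1850	NMe3	4
Cho	Me5	3.1850	NMe3	5
Cho	Me6	3.1850	NMe3	6
Cho	Me7	3.1850	NMe3	7
Cho	Me8	3.1850	NMe3	8
Cho	Me9	3.1850	NMe3	9
Cho	H1	4.0540	H1	10
Cho	H1p	4.0540	H1	10
Cho	H2	3.5010	H2	10
Cho	H2p	3.5010	H2	10
GPC	Me1	3.2120	NMe3	1
GPC	Me2	3.2120	NMe3	2
GPC	Me3	3.2120	NMe3	3
GPC	Me4	3.2120	NMe3	4
GPC	Me5	3.2120	NMe3	5
GPC	Me6	3.2120	NMe3	6
GPC	Me7	3.2120	NMe3	7
GPC	Me8	3.2120	NMe3	8
GPC	Me9	3.2120	NMe3	9
GPC	H7	4.3120	H7	10
GPC	H7p	4.3120	H7	10
GPC	H8	3.6590	H8	10
GPC	H8p	3.6590	H8	10
Cr	Me1	3.0270	CH3	1
Cr	Me2	3.0270	CH3	2
Cr	Me3	3.0270	CH3	3
Cr	H2a	3.9130	CH2	4
Cr	H2b	3.9130	CH2	5
Glu	H2	3.7433	H2	1
Glu	H3	2.0375	H3	1
Glu	H3p	2.1200	H3p	1
Glu	H4	2.3378	H4	1
Glu	H4p	2.3520	H4p	1
Gln	H2	3.7530	H2	1
Gln	H3	2.1290	H3	1
Gln	H3p	2.1090	H3p	1
Gln	H4	2.4320	H4	1
Gln	H4p	2.4540	H4p	1
mI	H1	3.5217	H13	1
mI	H2	4.0538	H2	1
mI	H3	3.5217	H13	1
mI	H4	3.6144	H46	1
mI	H5	3.2690	H5	1
mI	H6	3.6144	H46	1
Lac	H2	4.0974	H2	1
Lac	Me1	1.3142	CH3	1
Lac	Me2	1.3142	CH3	1
Lac	Me3	1.3142	CH3	1
GABA	H2	2.2840	H2	1
GABA	H2p	2.2840	H2	1
GABA	H3	1.8890	H3	1
GABA	H3p	1.8890	H3	1
GABA	H4	3.0128	H4	1
GABA	H4p	3.0128	H4	1
GSH	Hg1	3.7690	glyCH2	1
GSH	Hg2	3.7690	glyCH2	2
GSH	H2c	4.5608	H2c	3
GSH	H3c	2.9264	H3c	3
GSH	H3cp	2.9747	H3cp	3
GSH	H2g	3.7690	H2g	4
GSH	H3g	2.1590	H3g	4
GSH	H3gp	2.1460	H3gp	4
GSH	H4g	2.5100	H4g	4
GSH	H4gp	2.5600	H4gp	4
Gly	H1	3.5480	CH2	1
Gly	H2	3.5480	CH2	2
Ala	H2	3.7746	H2	1
Ala	Me1	1.4667	CH3	1
Ala	Me2	1.4667	CH3	1
Ala	Me3	1.4667	CH3	1
Glc	H1	4.6300	H1	1
Glc	H2	3.2300	H2	1
Glc	H3	3.4730	H3	1
Glc	H4	3.3870	H4	1
Glc	H5	3.4500	H5	1
Glc	H6	3.8820	H6	1
Glc	H6p	3.7070	H6p	1
Val	H2	3.5953	H2	1
Val	H3	2.2577	H3	1
Val	Mg1	1.0280	CH3g	1
Val	Mg2	1.0280	CH3g	1
Val	Mg3	1.0280	CH3g	1
Val	Mh1	0.9764	CH3h	1
Val	Mh2	0.9764	CH3h	1
Val	Mh3	0.9764	CH3h	1
2HG	H2	4.0220	H2	1
2HG	H3	1.8250	H3	1
2HG	H3p	1.9750	H3p	1
2HG	H4	2.2210	H4	1
2HG	H4p	2.2700	H4p	1
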