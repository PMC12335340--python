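# Scalar (J) couplings between protons of the shipped spin systems.
# Columns: metabolite, proton label i, proton label j, J (Hz).
# Couplings are symmetric; each pair is listed once. Pairs not listed are zero.
# Geminal couplings inside magnetically equivalent pairs are omitted (they do
# not affect the spectrum).
metabolite	proton_i	proton_j	j_hz
NAA	H2	H3	3.861
NAA	H2	H3p	9.821
NAA	H3	H3p	-15.592
NAAG	H2	H3	4.412
NAAG	H2	H3p	9.247
NAAG	H3	H3p	-15.910
NAAG	H2g	H3g	4.610
NAAG	H2g	H3gp	8.470
NAAG	H3g	H3gp	-14.280
NAAG	H3g	H4g	6.430
NAAG	H3g	H4gp	8.400
NAAG	H3gp	H4g	8.400
NAAG	H3gp	H4gp	6.430
NAAG	H4g	H4gp	-15.800
Cho	H1	H2	3.140
Cho	H1	H2p	6.979
Cho	H1p	H2	7.011
Cho	H1p	H2p	3.168
GPC	H7	H8	3.100
GPC	H7	H8p	5.900
GPC	H7p	H8	5.900
GPC	H7p	H8p	3.100
Glu	H2	H3	7.331
Glu	H2	H3p	4.651
Glu	H3	H3p	-14.849
Glu	H3	H4	6.413
Glu	H3	H4p	8.406
Glu	H3p	H4	8.478
Glu	H3p	H4p	6.875
Glu	H4	H4p	-15.915
Gln	H2	H3	5.847
Gln	H2	H3p	6.500
Gln	H3	H3p	-14.504
Gln	H3	H4	9.165
Gln	H3	H4p	6.347
Gln	H3p	H4	6.324
Gln	H3p	H4p	9.209
Gln	H4	H4p	-15.371
mI	H1	H2	2.889
mI	H2	H3	3.006
mI	H3	H4	9.997
mI	H4	H5	9.485
mI	H5	H6	9.482
mI	H1	H6	9.998
Lac	H2	Me1	6.933
Lac	H2	Me2	6.933
Lac	H2	Me3	6.933
GABA	H2	H3	7.678
GABA	H2	H3p	6.980
GABA	H2p	H3	6.980
GABA	H2p	H3p	7.678
GABA	H3	H4	7.755
GABA	H3	H4p	7.432
GABA	H3p	H4	7.432
GABA	H3p	H4p	7.755
GSH	H2c	H3c	7.090
GSH	H2c	H3cp	4.710
GSH	H3c	H3cp	-14.060
GSH	H2g	H3g	6.340
GSH	H2g	H3gp	6.360
GSH	H3g	H3gp	-15.480
GSH	H3g	H4g	6.700
GSH	H3g	H4gp	7.600
GSH	H3gp	H4g	7.600
GSH	H3gp	H4gp	6.700
GSH	H4g	H4gp	-15.920
Ala	H2	Me1	7.234
Ala	H2	Me2	7.234
Ala	H2	Me3	7.234
Glc	H1	H2	7.960
Glc	H2	H3	9.100
Glc	H3	H4	9.400
Glc	H4	H5	8.900
Glc	H5	H6	1.600
Glc	H5	H6p	5.400
Glc	H6	H6p	-12.300
Val	H2	H3	4.405
Val	H3	Mg1	6.971
Val	H3	Mg2	6.971
Val	H3	Mg3	6.971
Val	H3	Mh1	7.071
Val	H3	Mh2	7.071
Val	H3	Mh3	7.071
2HG	H2	H3	7.830
2HG	H2	H3p	4.300
2HG	H3	H3p	-14.000
2HG	H3	H4	10.700
2HG	H3	H4p	6.000
2HG	H3p	H4	5.300
2HG	H3p	H4p	10.900
2HG	H4	H4p	-15.000
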