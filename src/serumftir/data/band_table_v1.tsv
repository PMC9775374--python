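# serumftir band reference table, version 1
# Control band centers (cm-1), Gaussian sigma (cm-1), amide-I-anchored relative
# absorbance per group, and per-band search half-window for SD-IR detection.
# Group columns give the group's band center and relative absorbance; the
# generator derives center_delta = center - control_center and
# amplitude_factor = relabs / control_relabs.
name	assignment	control_center	sigma	control_relabs	half_window	lc_center	lc_relabs	gc_center	gc_relabs	cc_center	cc_relabs
amide A	nu(N-H)	3346.3	25.0	1.00	25.0	3366.2	1.00	3364.2	1.00	3364.2	1.00
nu_as(CH3)	nu_as(C-H) lipid	2954.8	5.5	1.07	10.0	2962.4	1.06	2956.7	1.12	2960.6	0.94
nu_as(CH2)	nu_as(C-H) lipid	2925.8	5.5	0.83	8.0	2927.8	1.00	2925.8	1.06	2923.9	0.82
amide I	nu(C=O)	1637.6	14.0	1.00	8.0	1637.5	1.0002	1639.4	1.00	1638.2	1.00
amide II	delta(N-H)+nu(C-N)	1546.9	8.0	1.03	10.0	1548.8	0.98	1544.9	1.04	1554.5	0.79
delta(CH2)	delta(C-H) lipid	1452.3	10.0	0.83	10.0	1456.2	1.11	1455.6	1.05	1460.0	0.83
nu_s(COO-)	nu_s(C=O) carboxylate	1397.6	10.0	1.02	8.0	1400.0	0.95	1398.3	1.05	1402.2	0.73
amide III	nu(C-N)+delta(N-H)	1311.5	10.0	1.02	8.0	1315.4	0.93	1309.6	1.26	1313.4	0.73
nu_as(PO2-)	nu_as(P=O) nucleic acid	1247.2	10.0	0.91	8.0	1245.9	0.87	1247.9	1.00	1244.0	0.67
nu_s(C-O-C)	nu_s(C-O-C) carbohydrate	1166.9	10.0	0.91	8.0	1168.8	0.83	1164.9	1.00	1167.3	0.67
nu_s(PO2-)	nu_s(P=O) nucleic acid	1091.6	5.0	0.91	12.0	1089.7	0.92	1083.9	1.00	1081.8	0.58
delta(N-H) 1508	delta(N-H) CEA-linked	1506.3	7.0	0.40	8.0	1508.1	0.402960	1508.0	0.402880	1508.1	0.402920
nu(C-O-H) 1040	nu(C-O-H) CEA-linked	1040.1	8.0	0.40	8.0	1041.9	0.402720	1039.7	0.402760	1041.2	0.40
nu_s(NH-C=O) 1117	nu_s(NH-C=O) sugar ring	1116.4	5.0	0.45	8.0	1119.4	0.453060	1119.4	0.453015	1118.2	0.452970
delta_out(N-H) 986	delta_out(N-H) sugar ring	983.1	8.0	0.45	8.0	984.8	0.453150	986.1	0.453105	986.1	0.453150
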