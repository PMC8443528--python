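aa	hydrophobicity	volume	polarity	charge	hbond	flexibility	helix_propensity	sheet_propensity
A	1.8	88.6	8.1	0	0	0.984	0.00	0.83
C	2.5	108.5	5.5	0	1	0.906	0.68	1.19
D	-3.5	111.1	13.0	-1	4	1.068	0.69	0.54
E	-3.5	138.4	12.3	-1	4	1.094	0.40	0.37
F	2.8	189.9	5.2	0	0	0.915	0.54	1.38
G	-0.4	60.1	9.0	0	0	1.031	1.00	0.75
H	-3.2	153.2	10.4	0	3	0.950	0.61	0.87
I	4.5	166.7	5.2	0	0	0.927	0.41	1.60
K	-3.9	168.6	11.3	1	3	1.102	0.26	0.74
L	3.8	166.7	4.9	0	0	0.935	0.21	1.30
M	1.9	162.9	5.7	0	1	0.952	0.24	1.05
N	-3.5	114.1	11.6	0	4	1.048	0.65	0.89
P	-1.6	112.7	8.0	0	0	1.049	3.16	0.55
Q	-3.5	143.8	10.5	0	4	1.037	0.39	1.10
R	-4.5	173.4	10.5	1	5	1.008	0.21	0.93
S	-0.8	89.0	9.2	0	2	1.046	0.50	0.75
T	-0.7	116.1	8.6	0	2	0.997	0.66	1.19
V	4.2	140.0	5.9	0	0	0.931	0.61	1.70
W	-0.9	227.8	5.4	0	1	0.904	0.49	1.37
Y	-1.3	193.6	6.2	0	2	0.929	0.53	1.47
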