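gene	fc_stim	fc_C01L_F03	fc_STATTIC	fc_STX-0119
CXCL10	9298.61	615.79	15.14	223.90
CCL8	2118.86	6.83	6.31	0.79
UBD	1860.83	129.28	2.09	62.19
CXCL9	1565.00	2.26	1.00	6.31
GBP4	793.16	38.79	16.30	8.61
GBP5	435.89	20.26	5.26	11.63
OAS2	329.65	2.61	6.29	1.48
VCAM1	326.83	33.01	1.36	8.12
CCL7	289.01	1.00	3.41	1.00
INDO	209.33	1.00	1.80	1.00
MMP3	192.62	2.22	28.96	2.89
IDO1	178.80	1.62	6.03	1.42
CCL3L3	165.18	4.69	1.52	20.25
OASL	160.22	3.99	1.21	14.16
LYPD5	127.07	6.75	6.90	7.66
LTB	125.33	1.00	0.75	0.95
MMP12	111.79	0.70	0.70	0.70
IFI44L	100.04	1.14	1.14	1.21
LOC730249	91.23	0.60	0.96	0.78
CD74	88.67	1.18	0.76	0.84
LOC100129681	76.64	1.31	2.35	0.18
MX2	68.99	0.40	0.74	1.23
DLL1	68.78	3.39	10.80	8.11
C1S	64.57	4.22	5.98	2.39
TNFSF10	64.45	0.67	1.22	0.21
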