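sequence	pfs_l1	pfs_l2	pfs_l3	pfs_l4
VMP + DRd + Pd + Kd	1.97	4.74	0.46	0.42
VMP + DRd + Kd + Pd	1.97	4.74	0.72	0.38
Rd + VCd + D + Pd	4.13	0.95	0.71	0.38
Rd + VCd + Pd + D	4.13	0.95	0.46	0.59
DRd + PVd + Kd + Vd	7.48	1.29	0.71	0.28
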