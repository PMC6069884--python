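name	GP_fc	XZ29_fc	exclusive_to
ata-miR156a-3p	0.20	0.89
ata-miR156a-5p	-0.49	0.91
bdi-miR156h-3p	0.33	-1.15
hvu-miR159a	-0.21	-0.67
hvu-MIR159a-5p	-0.44	-1.36
osa-miR319a-3p.2-3p	-0.35	0.76
ata-miR160a-5p	-0.44	-0.77
ata-miR164c-3p	0.37	0.63
hvu-miR166a	-0.82	-1.61
ata-miR166a-3p	-0.54	-1.84
ata-miR166a-5p	-0.71	-0.03
ata-miR166d-5p	-0.53	-0.29
ata-miR167a-5p	-0.63	-0.17
ata-miR167b-3p	-0.92	-0.71
ata-miR167b-5p	0.58	-0.23
tae-miR167c-5p	0.64	-2.00
ata-miR167f-3p	0.29	0.84
hvu-miR168-3p	-0.71	1.04
hvu-miR168-5p	-0.55	-0.83
ata-miR169i-5p	0.42	-1.58
ata-miR169d-5p	-0.46	-0.86
ata-MIR169d-3p	-0.91	-1.82
ata-miR169h-3p	-0.81	0.18
ata-miR171b-5p	-0.70	0.14
ata-miR171a-5p	-1.42	-1.15
ata-miR172b-3p	-0.63	-0.55
ata-miR390-5p	-1.86	-0.56
ata-miR393-5p	-0.16	-1.57
ata-miR394-5p	-1.18	-0.30
ata-miR396a-5p	0.16	-1.20
ata-miR396e-5p	0.51	-1.46
osa-miR444a-3p.2	-0.14	-0.82
ppt-miR477h	1.34	2.83
osa-miR827	-0.46	-1.26
ata-miR1432-5p	-1.56	0.21
hvu-miR5048a	0.36	-1.68
tae-miR7757-5p	0.66	-0.55
tae-MIR9662a-5p	-0.38	2.33
ata-MIR9863a-5p	0.58	1.39
ppt-miR894	-0.02	2.08
hvu-miR5051	0.04	-0.92
bdi-miR5054	-1.98	2.07
osa-miR5072	-1.21	1.43
gma-miR6300	0.86	3.08
ptc-miR6478	1.04	3.46
ath-miR8175	-2.46	1.96
PC-miR1	0.00	-0.73	XZ29
PC-miR2	0.00	1.26	XZ29
PC-miR4	2.11	0.00	GP
PC-miR6	-0.69	0.70
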