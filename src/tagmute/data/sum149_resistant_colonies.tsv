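sgrnas	colonies
PARP1_ex16	5
PARP1_ex19	1
PARP1_ex22	1
PARP1_ex19;MCF2L_ex2	1
PARP1_ex22;JPH4_ex3	1
RABGAP1_ex8	1
ND	2
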