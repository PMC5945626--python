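clone_id	sgrnas
BR1	Parp1#1;Tmed5
BR2	Parp1#1
BR3	Gpd2
BR4	Tbx20;Gpr89;Pde4d;Arhgap12
BR5	Trp53;Csmd1
BR6	Parp1#2;Apol6
BR7	Parp1#1;Abca14;Dtnb;Tmed5
BR8	Parp1#2;Lemd1;Slmo1
BR9	Parp1#2
BR10	Parp1#1;Spock1;P2ry6;AW209491
BR11	Tdg;Gm5597
BR12	Abca14;Dtnb
BR13	Parp1#1;Nwd1;Scn10a
BR14	Tdg;Gm5597;Tmed5
BR15	ND
BR16	Defb25
BR17	ND
BR18	Traf3ip1;Hkdc1;Gm4876
BR19	Dnajb11;Scaf8;Acbd3;Msh2
BR20	ND
BR21	Trp53;Csmd3;Chst15
BR22	Cyp2r1;Tmem69
BR23	ND
BR24	Tdg
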