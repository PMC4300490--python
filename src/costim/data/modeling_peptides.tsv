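ppep_id	protein	known_function
Hog1_T174_Y176	Hog1	1
Hog1_Y176	Hog1	1
Ste20_T511	Ste20	1
Ste20_S195	Ste20	1
Ste20_T573	Ste20	1
Ste20_T203_T207	Ste20	1
Ste20_S418	Ste20	1
Ste20_S169	Ste20	0
Ste20_T546	Ste20	0
Pbs2_S68	Pbs2	1
Pbs2_S248	Pbs2	1
Pbs2_S269	Pbs2	1
Fus3_T180_Y182	Fus3	1
Hot1_S153	Hot1	1
Ptp2_S258	Ptp2	1
Gpd1_S24_S27	Gpd1	1
Ste11_S323	Ste11	1
Ste50_S202	Ste50	1
Ssk1_S673	Ssk1	1
Ssk2_S53_S57	Ssk2	1
Ypk1_S644_S653	Ypk1	1
Bit61_S139_S144	Bit61	1
Nbp2_S196	Nbp2	1
Dig1_S272	Dig1	0
Dig1_S395	Dig1	0
Dig2_T225	Dig2	1
Ste12_S400	Ste12	1
Far1_S114	Far1	1
Sko1_S108	Sko1	0
Rck2_S45	Rck2	0
Fps1_S181	Fps1	0
Sic1_T173	Sic1	0
Tec1_S273	Tec1	0
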