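gene	start	end	strand	frame
MT-ND1	3307	4262	H	0
MT-ND2	4470	5511	H	0
MT-CO1	5904	7445	H	0
MT-CO2	7586	8269	H	0
MT-ATP8	8366	8572	H	0
MT-ATP6	8527	9207	H	0
MT-CO3	9207	9990	H	0
MT-ND3	10059	10404	H	0
MT-ND4L	10470	10766	H	0
MT-ND4	10760	12137	H	0
MT-ND5	12337	14148	H	0
MT-ND6	14149	14673	L	0
MT-CYB	14747	15887	H	0
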