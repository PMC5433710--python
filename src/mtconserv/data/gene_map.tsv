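gene	start	end	strand
mt-ND1	3307	4262	+
mt-ND2	4470	5511	+
mt-CO1	5904	7445	+
mt-CO2	7586	8269	+
mt-ATP8	8366	8572	+
mt-ATP6	8527	9207	+
mt-CO3	9207	9990	+
mt-ND3	10059	10404	+
mt-ND4L	10470	10766	+
mt-ND4	10760	12137	+
mt-ND5	12337	14148	+
mt-ND6	14149	14673	-
mt-CYB	14747	15887	+
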