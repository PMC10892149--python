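sample_id,description,Vb_expected,Vb_actual,Se_expected,Se_actual,Sa_expected,Sa_actual,Vf_expected,Vf_actual
1,"VF swab spiked with semen (100 uL 1:100)",-,-,+,-,-,+,+,+
2,"MB swab spiked with semen (50 uL 1:100)",+,+,+,-,-,+,+,+
3,"MB swab",+,+,-,-,-,-,+,+
4,"Nasal swab spiked with saliva (100 uL)",-,+,-,-,+,+,-,-
5,"VF smear on cloth, spiked with male saliva (100 uL)",-,-,-,-,+,+,+,+
6,"Blood smear on jeans",+,+,-,-,-,-,-,-
7,"VF smear on jeans, spiked with semen (100 uL 1:100)",-,+,+,-,-,-,+,+
8,"4 yr old blood on filter paper",+,+,-,-,-,-,-,-
9,"4 yr old semen on filter paper",-,-,+,-,-,+,-,-
10,"Nasal swab",-,-,-,-,-,-,-,-
11,"Liquid breast milk",-,-,-,-,-,-,-,-
12,"Breast milk on swab, spiked with saliva (100 uL)",-,-,-,-,+,+,-,+
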