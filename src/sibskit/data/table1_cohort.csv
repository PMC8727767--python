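patient_id,age_bin,sex,max_bsr,max_gcs,gose_discharge,days_discharge,gose_chronic,days_chronic,barbiturates,propofol,usable_sections,total_sections
1,18-25,M,0.9997,8,3,17,7,183,TRUE,FALSE,6,6
2,25-40,F,0.9996,14,3,2,7,188,TRUE,TRUE,4,5
3,25-40,M,0.9996,8,3,24,8,180,TRUE,FALSE,7,7
4,55-70,F,0.9323,14,3,23,,,TRUE,FALSE,6,6
5,25-40,M,0.9313,4,3,38,3,246,TRUE,TRUE,6,9
6,40-55,M,0.9275,7,3,29,5,203,TRUE,FALSE,7,7
7,18-25,M,0.8747,11,3,30,6,179,TRUE,FALSE,5,6
8,18-25,M,0.8708,10,3,24,7,181,TRUE,FALSE,4,6
9,25-40,M,0.4674,4,2,23,3,183,TRUE,FALSE,6,7
10,55-70,M,0.422,8,2,16,,,FALSE,TRUE,5,6
11,40-55,M,0.148,11,3,35,2,172,FALSE,TRUE,6,6
12,40-55,M,0.1467,14,3,33,5,189,FALSE,TRUE,5,5
13,25-40,M,0.1376,10,2,23,3,179,FALSE,TRUE,6,6
14,55-70,F,0.0555,10,1,30,1,,FALSE,FALSE,6,7
15,70-85,M,0.0548,15,3,13,6,182,FALSE,FALSE,3,3
16,40-55,M,0.0316,11,2,24,3,182,FALSE,FALSE,3,4
17,40-55,M,0.0254,14,4,20,5,184,TRUE,TRUE,2,3
18,25-40,M,0.0193,14,3,4,7,179,FALSE,FALSE,3,3
19,18-25,M,0.0181,14,3,5,8,184,FALSE,FALSE,1,1
20,25-40,M,0.017,7,2,24,2,161,FALSE,TRUE,8,8
21,70-85,M,0.014,14,3,8,5,177,FALSE,TRUE,3,5
22,55-70,M,0.0098,14,3,24,3,224,FALSE,TRUE,7,7
23,25-40,M,0.0095,6,1,17,1,,FALSE,TRUE,5,5
24,25-40,M,0.0076,9,2,20,2,177,FALSE,TRUE,4,4
25,40-55,M,0.0055,14,4,14,6,174,FALSE,FALSE,3,3
26,25-40,M,0.0039,10,3,20,6,182,FALSE,FALSE,5,6
27,25-40,M,0.0028,10,2,26,3,177,FALSE,TRUE,2,6
28,55-70,F,0.002,14,3,11,3,181,FALSE,TRUE,3,5
29,55-70,M,0.0015,10,2,23,3,279,FALSE,TRUE,7,8
30,55-70,M,0.0008,14,3,18,7,318,FALSE,TRUE,3,3
31,18-25,M,0.0001,6,2,24,3,164,FALSE,FALSE,4,4
32,18-25,F,0,8,2,51,3,192,FALSE,TRUE,2,2
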