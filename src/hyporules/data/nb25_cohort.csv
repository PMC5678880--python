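tumor_id,cluster,sex,age_months,inss_stage,outcome,histology,mycn_amplified,HIF1A_percent_bin,HIF1A_intensity,HIF1A_medium_resolution,PDK1_percent_bin,PDK1_intensity,PDK1_medium_resolution,PHD3_percent_bin,PHD3_intensity,PHD3_medium_resolution
1,hypoxic,male,16,4,Relapsed,UH,no,71–100%,unknown,not_applicable,71–100%,unknown,not_applicable,1–20%,unknown,not_applicable
2,hypoxic,male,17,4,Deceased,UH,yes,71–100%,unknown,not_applicable,71–100%,unknown,not_applicable,1–20%,unknown,not_applicable
3,hypoxic,male,43,4,Deceased,UH,yes,71–100%,unknown,not_applicable,71–100%,unknown,not_applicable,1–20%,unknown,not_applicable
4,hypoxic,male,55,4,Deceased,UH,no,71–100%,unknown,not_applicable,51–70%,unknown,not_applicable,1–20%,unknown,not_applicable
5,hypoxic,male,9,4S,Resid. disease,FH,yes,71–100%,unknown,not_applicable,71–100%,unknown,not_applicable,1–20%,unknown,not_applicable
6,hypoxic,female,21,3,Deceased,UH,yes,71–100%,unknown,not_applicable,51–70%,unknown,not_applicable,<1%,unknown,not_applicable
7,hypoxic,male,40,3,Relapsed,UH,no,51–70%,unknown,not_applicable,21–50%,unknown,low,<1%,unknown,not_applicable
8,hypoxic,female,69,1,Cont. remiss.,FH,yes,71–100%,unknown,not_applicable,51–70%,unknown,not_applicable,1–20%,unknown,not_applicable
9,normoxic,male,0.71,4,Resid. disease,FH,yes,1–20%,unknown,not_applicable,1–20%,unknown,not_applicable,1–20%,unknown,not_applicable
10,normoxic,male,7,4S,Resid. disease,FH,no,1–20%,unknown,not_applicable,1–20%,unknown,not_applicable,51–70%,unknown,not_applicable
11,normoxic,male,5,3,Cont. remiss.,FH,no,1–20%,unknown,not_applicable,<1%,unknown,not_applicable,71–100%,unknown,not_applicable
12,normoxic,male,6,3,Cont. remiss.,FH,no,1–20%,unknown,not_applicable,<1%,unknown,not_applicable,71–100%,unknown,not_applicable
13,normoxic,female,11,3,Resid. disease,FH,no,1–20%,unknown,not_applicable,21–50%,unknown,high,51–70%,unknown,not_applicable
14,normoxic,male,146,3,Deceased,UH,yes,1–20%,unknown,not_applicable,1–20%,unknown,not_applicable,51–70%,unknown,not_applicable
15,normoxic,female,7,2B,Cont. remiss.,FH,no,<1%,unknown,not_applicable,1–20%,unknown,not_applicable,71–100%,unknown,not_applicable
16,normoxic,male,10,2B,Resid. disease,FH,no,1–20%,unknown,not_applicable,<1%,unknown,not_applicable,21–50%,unknown,low
17,normoxic,female,10,2B,Cont. remiss.,FH,no,<1%,unknown,not_applicable,1–20%,unknown,not_applicable,71–100%,unknown,not_applicable
18,normoxic,male,0.5,2A,Cont. remiss.,FH,no,1–20%,unknown,not_applicable,1–20%,unknown,not_applicable,71–100%,unknown,not_applicable
19,normoxic,male,4,2A,Cont. remiss.,FH,no,1–20%,unknown,not_applicable,1–20%,unknown,not_applicable,71–100%,unknown,not_applicable
20,normoxic,female,2,1,Cont. remiss.,FH,no,<1%,unknown,not_applicable,1–20%,unknown,not_applicable,51–70%,unknown,not_applicable
21,normoxic,male,3,1,Cont. remiss.,FH,no,1–20%,unknown,not_applicable,1–20%,unknown,not_applicable,51–70%,unknown,not_applicable
22,normoxic,male,3,1,Cont. remiss.,FH,no,1–20%,unknown,not_applicable,<1%,unknown,not_applicable,71–100%,unknown,not_applicable
23,normoxic,male,7,1,Cont. remiss.,FH,no,21–50%,unknown,high,1–20%,unknown,not_applicable,71–100%,unknown,not_applicable
24,normoxic,female,24,1,Resid. disease,FH,no,21–50%,unknown,high,21–50%,unknown,high,71–100%,unknown,not_applicable
25,normoxic,female,53,1,Cont. remiss.,FH,no,51–70%,unknown,not_applicable,1–20%,unknown,not_applicable,71–100%,unknown,not_applicable
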