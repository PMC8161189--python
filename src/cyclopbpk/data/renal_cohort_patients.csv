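patient_id,sex,age_years,body_weight_kg,body_height_cm
1,female,64,71,164
2,female,59,68,165
3,male,48,111,180
4,male,66,86,176
5,male,22,106,181
6,female,48,64,167
7,female,59,80,165
8,male,58,103,178
9,female,36,48,167
10,female,49,63,167
11,female,41,53,167
12,male,50,94,179
13,female,49,69,167
14,female,24,106,168
15,female,62,55,164
16,female,51,74,166
17,male,36,99,180
18,male,30,75,180
19,male,57,76,178
20,female,54,53,166
21,male,27,66,181
22,male,42,78,180
23,male,46,93,180
24,male,37,77,180
25,female,43,64,167
26,female,41,59,167
27,female,44,62,167
28,male,41,77,180
29,female,45,76,167
30,male,57,95,178
31,male,42,63,180
32,male,52,81,179
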