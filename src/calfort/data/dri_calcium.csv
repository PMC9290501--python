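label,sex,pregnant,age_min_years,age_max_years,ear_mg,ul_mg
0.5 <= age < 1,any,false,0.5,1,270,1500
1 <= age < 4,any,false,1,4,400,2500
4 <= age < 9,any,false,4,9,640,2500
9 <= age < 14,female,false,9,14,1100,3000
14 <= age < 19,female,false,14,19,1100,3000
19 <= age < 31,female,false,19,31,800,2500
31 <= age < 51,female,false,31,51,800,2500
51 <= age < 71,female,false,51,71,1000,2000
age >= 71,female,false,71,200,1000,2000
9 <= age < 14,male,false,9,14,1100,3000
14 <= age < 19,male,false,14,19,1100,3000
19 <= age < 31,male,false,19,31,800,2500
31 <= age < 51,male,false,31,51,800,2500
51 <= age < 71,male,false,51,71,800,2000
age >= 71,male,false,71,200,1000,2000
14 <= age < 19 (pregnant),female,true,14,19,1100,3000
19 <= age < 31 (pregnant),female,true,19,31,800,2500
31 <= age < 51 (pregnant),female,true,31,51,800,2500
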