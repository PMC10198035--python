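age,race,count
<18,NH White,387
<18,NH Black,274
<18,NH AIAN,15
<18,NH Asian,36
<18,NH NHPI,11
<18,NH Mix,30
<18,Hispanic,303
18-29,NH White,2263
18-29,NH Black,1492
18-29,NH AIAN,187
18-29,NH Asian,190
18-29,NH NHPI,49
18-29,NH Mix,73
18-29,Hispanic,2015
30-39,NH White,6661
30-39,NH Black,4144
30-39,NH AIAN,560
30-39,NH Asian,558
30-39,NH NHPI,151
30-39,NH Mix,157
30-39,Hispanic,5919
40-49,NH White,17269
40-49,NH Black,8937
40-49,NH AIAN,1021
40-49,NH Asian,1206
40-49,NH NHPI,265
40-49,NH Mix,309
40-49,Hispanic,13981
50-64,NH White,97418
50-64,NH Black,35753
50-64,NH AIAN,3198
50-64,NH Asian,5312
50-64,NH NHPI,715
50-64,NH Mix,952
50-64,Hispanic,43657
65-74,NH White,141409
65-74,NH Black,37765
65-74,NH AIAN,2901
65-74,NH Asian,7423
65-74,NH NHPI,501
65-74,NH Mix,913
65-74,Hispanic,38422
>74,NH White,380630
>74,NH Black,54576
>74,NH AIAN,3210
>74,NH Asian,16504
>74,NH NHPI,449
>74,NH Mix,1380
>74,Hispanic,56711
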