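compound_id,name,series,dc50_nM,dc50_censored_above_nM,dmax
1,,SMARCA2,8,,98
2,,SMARCA2,95,,95
3,,SMARCA2,,10000,
4,,SMARCA2,99,,96
5,,SMARCA2,112,,96
6,AU-15330,SMARCA2,85,,96
7,,SMARCA2,850,,55
8,,SMARCA2,379,,80
9,,SMARCA2,372,,74
10,,SMARCA2,469,,65
11,,SMARCA2,221,,53
12,,BRD4,518,,91
13,,BRD4,726,,78
14,,BRD4,2260,,69
15,,BRD4,,10000,
16,,BRD4,,10000,
17,MZ1,BRD4,40,,98
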