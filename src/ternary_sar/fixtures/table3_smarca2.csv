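compound_id,name,target_domain,k_lp_nM,k_lpt_nM,alpha,auc,initial_rate,k_lpt_approximate
1,,SMARCA2-BD,60,4.7,12.8,13,1.9,0
2,,SMARCA2-BD,210,33,6.5,28,2.02,0
3,,SMARCA2-BD,58,500,0.1,,,1
4,,SMARCA2-BD,166,64,2.6,26,2.06,0
5,,SMARCA2-BD,84.7,46.8,1.8,28,1.9,0
6,AU-15330,SMARCA2-BD,11,5.6,2,26,3.5,0
7,,SMARCA2-BD,9,80,0.11,122,0.78,0
8,,SMARCA2-BD,7,27,0.26,75,1.34,0
9,,SMARCA2-BD,25,77,0.32,85,0.98,0
10,,SMARCA2-BD,60,250,0.24,100,0.56,0
11,PROTAC 2,SMARCA2-BD,59,108,0.55,119,0.25,0
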