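compound_id,name,target_domain,k_lp_nM,k_lpt_nM,alpha,auc,initial_rate,k_lpt_approximate
12,,BRD4-BD2,22,6,3.7,192,1.38,0
13,,BRD4-BD2,17,10,1.7,309,0.76,0
14,,BRD4-BD2,26,26.5,1,460,0.46,0
15,,BRD4-BD2,31,39,0.8,733,0.21,0
16,,BRD4-BD2,33,49,0.7,900,0.08,0
17,MZ1,BRD4-BD2,20.5,1.5,13.7,39,1.95,0
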