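compound_id,name,target_domain,k_lp_nM,k_lpt_nM,alpha,auc,initial_rate,k_lpt_approximate
12,,BRD4-BD1,22,31,0.7,192,1.38,0
13,,BRD4-BD1,17,29,0.6,309,0.76,0
14,,BRD4-BD1,26,33,0.8,460,0.46,0
15,,BRD4-BD1,31,26.5,1.2,733,0.21,0
16,,BRD4-BD1,33,33,1,900,0.08,0
17,MZ1,BRD4-BD1,20.5,15,1.4,39,1.95,0
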