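id,name,segment,n_treated,nnt,benefit_score,annual_cost
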