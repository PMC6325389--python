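h2,n_ref,daughters,criterion,percent_m,percent_f,statistic,value,note
0.1,,50,own_ebv,5.0,70.0,equivalence,0.183,
0.1,,50,own_ebv,5.0,100.0,equivalence,0.208,
0.1,,50,pa,5.0,70.0,equivalence,0.19,
0.1,,50,pa,5.0,100.0,equivalence,0.208,
0.1,,50,own_ebv,30.0,70.0,equivalence,0.178,
0.1,,50,own_ebv,30.0,100.0,equivalence,0.203,
0.1,,50,pa,30.0,70.0,equivalence,0.186,
0.1,,50,pa,30.0,100.0,equivalence,0.203,
0.3,,50,own_ebv,5.0,70.0,equivalence,0.379,
0.3,,50,own_ebv,5.0,100.0,equivalence,0.49,
0.3,,50,pa,5.0,70.0,equivalence,0.422,
0.3,,50,pa,5.0,100.0,equivalence,0.49,
0.3,,50,own_ebv,30.0,70.0,equivalence,0.363,
0.3,,50,own_ebv,30.0,100.0,equivalence,0.469,
0.3,,50,pa,30.0,70.0,equivalence,0.403,printed value differs from recomputation by one unit in the last decimal
0.3,,50,pa,30.0,100.0,equivalence,0.469,
0.5,,50,own_ebv,5.0,70.0,equivalence,0.562,
0.5,,50,own_ebv,5.0,100.0,equivalence,0.811,
0.5,,50,pa,5.0,70.0,equivalence,0.669,
0.5,,50,pa,5.0,100.0,equivalence,0.811,
0.5,,50,own_ebv,30.0,70.0,equivalence,0.53,printed value differs from recomputation by one unit in the last decimal
0.5,,50,own_ebv,30.0,100.0,equivalence,0.763,
0.5,,50,pa,30.0,70.0,equivalence,0.63,
0.5,,50,pa,30.0,100.0,equivalence,0.763,
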