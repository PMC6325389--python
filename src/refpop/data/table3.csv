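h2,n_ref,daughters,criterion,percent_m,percent_f,statistic,value,note
0.1,,50,progeny_test,,,reliability,0.562,
0.1,,50,own_ebv,,,reliability,0.236,
0.1,,50,pa,,,reliability,0.165,
0.3,,50,progeny_test,,,reliability,0.802,
0.3,,50,own_ebv,,,reliability,0.447,
0.3,,50,pa,,,reliability,0.276,
0.5,,50,progeny_test,,,reliability,0.877,
0.5,,50,own_ebv,,,reliability,0.604,
0.5,,50,pa,,,reliability,0.344,
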