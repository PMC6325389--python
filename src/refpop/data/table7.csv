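h2,n_ref,daughters,criterion,percent_m,percent_f,statistic,value,note
0.1,10000,100,own_ebv,5.0,70.0,bulls_only,0.497,
0.1,10000,100,own_ebv,5.0,70.0,cows_only,0.126,
0.1,10000,100,own_ebv,5.0,70.0,combined,0.531,
0.1,10000,100,own_ebv,5.0,100.0,bulls_only,0.497,
0.1,10000,100,own_ebv,5.0,100.0,cows_only,0.143,
0.1,10000,100,own_ebv,5.0,100.0,combined,0.536,
0.1,10000,100,own_ebv,30.0,70.0,bulls_only,0.505,
0.1,10000,100,own_ebv,30.0,70.0,cows_only,0.126,
0.1,10000,100,own_ebv,30.0,70.0,combined,0.538,printed value differs from recomputation by one unit in the last decimal
0.1,10000,100,own_ebv,30.0,100.0,bulls_only,0.505,
0.1,10000,100,own_ebv,30.0,100.0,cows_only,0.143,
0.1,10000,100,own_ebv,30.0,100.0,combined,0.542,
0.1,20000,100,own_ebv,5.0,70.0,bulls_only,0.497,
0.1,20000,100,own_ebv,5.0,70.0,cows_only,0.223,
0.1,20000,100,own_ebv,5.0,70.0,combined,0.56,
0.1,20000,100,own_ebv,5.0,100.0,bulls_only,0.497,
0.1,20000,100,own_ebv,5.0,100.0,cows_only,0.25,
0.1,20000,100,own_ebv,5.0,100.0,combined,0.569,
0.1,20000,100,own_ebv,30.0,70.0,bulls_only,0.505,
0.1,20000,100,own_ebv,30.0,70.0,cows_only,0.223,
0.1,20000,100,own_ebv,30.0,70.0,combined,0.566,
0.1,20000,100,own_ebv,30.0,100.0,bulls_only,0.505,
0.1,20000,100,own_ebv,30.0,100.0,cows_only,0.25,
0.1,20000,100,own_ebv,30.0,100.0,combined,0.575,
0.3,10000,100,own_ebv,5.0,70.0,bulls_only,0.524,
0.3,10000,100,own_ebv,5.0,70.0,cows_only,0.277,
0.3,10000,100,own_ebv,5.0,70.0,combined,0.598,
0.3,10000,100,own_ebv,5.0,100.0,bulls_only,0.524,
0.3,10000,100,own_ebv,5.0,100.0,cows_only,0.333,
0.3,10000,100,own_ebv,5.0,100.0,combined,0.616,
0.3,10000,100,own_ebv,30.0,70.0,bulls_only,0.537,
0.3,10000,100,own_ebv,30.0,70.0,cows_only,0.277,
0.3,10000,100,own_ebv,30.0,70.0,combined,0.607,
0.3,10000,100,own_ebv,30.0,100.0,bulls_only,0.537,
0.3,10000,100,own_ebv,30.0,100.0,cows_only,0.333,
0.3,10000,100,own_ebv,30.0,100.0,combined,0.624,
0.3,20000,100,own_ebv,5.0,70.0,bulls_only,0.524,
0.3,20000,100,own_ebv,5.0,70.0,cows_only,0.434,
0.3,20000,100,own_ebv,5.0,70.0,combined,0.652,
0.3,20000,100,own_ebv,5.0,100.0,bulls_only,0.524,
0.3,20000,100,own_ebv,5.0,100.0,cows_only,0.5,
0.3,20000,100,own_ebv,5.0,100.0,combined,0.67,misprint: inconsistent with the printed per-group reliabilities in the same row
0.3,20000,100,own_ebv,30.0,70.0,bulls_only,0.537,
0.3,20000,100,own_ebv,30.0,70.0,cows_only,0.434,
0.3,20000,100,own_ebv,30.0,70.0,combined,0.658,
0.3,20000,100,own_ebv,30.0,100.0,bulls_only,0.537,
0.3,20000,100,own_ebv,30.0,100.0,cows_only,0.5,
0.3,20000,100,own_ebv,30.0,100.0,combined,0.683,
0.5,10000,100,own_ebv,5.0,70.0,bulls_only,0.518,
0.5,10000,100,own_ebv,5.0,70.0,cows_only,0.365,
0.5,10000,100,own_ebv,5.0,70.0,combined,0.623,
0.5,10000,100,own_ebv,5.0,100.0,bulls_only,0.518,
0.5,10000,100,own_ebv,5.0,100.0,cows_only,0.455,
0.5,10000,100,own_ebv,5.0,100.0,combined,0.656,
0.5,10000,100,own_ebv,30.0,70.0,bulls_only,0.534,
0.5,10000,100,own_ebv,30.0,70.0,cows_only,0.365,
0.5,10000,100,own_ebv,30.0,70.0,combined,0.633,
0.5,10000,100,own_ebv,30.0,100.0,bulls_only,0.534,
0.5,10000,100,own_ebv,30.0,100.0,cows_only,0.455,
0.5,10000,100,own_ebv,30.0,100.0,combined,0.664,
0.5,20000,100,own_ebv,5.0,70.0,bulls_only,0.518,
0.5,20000,100,own_ebv,5.0,70.0,cows_only,0.535,
0.5,20000,100,own_ebv,5.0,70.0,combined,0.69,
0.5,20000,100,own_ebv,5.0,100.0,bulls_only,0.518,
0.5,20000,100,own_ebv,5.0,100.0,cows_only,0.625,
0.5,20000,100,own_ebv,5.0,100.0,combined,0.733,
0.5,20000,100,own_ebv,30.0,70.0,bulls_only,0.534,
0.5,20000,100,own_ebv,30.0,70.0,cows_only,0.535,
0.5,20000,100,own_ebv,30.0,70.0,combined,0.697,
0.5,20000,100,own_ebv,30.0,100.0,bulls_only,0.534,
0.5,20000,100,own_ebv,30.0,100.0,cows_only,0.625,
0.5,20000,100,own_ebv,30.0,100.0,combined,0.738,
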