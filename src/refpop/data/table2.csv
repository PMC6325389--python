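h2,n_ref,daughters,criterion,percent_m,percent_f,statistic,value,printed_label,note
0.1,5000,,own_ebv,,70.0,reliability,0.0683,pa,
0.1,5000,,own_ebv,,80.0,reliability,0.0699,pa,
0.1,5000,,own_ebv,,90.0,reliability,0.0721,pa,
0.1,5000,,pa,,100.0,reliability,0.0769,pa,
0.1,5000,,pa,,70.0,reliability,0.0709,own_ebv,
0.1,5000,,pa,,80.0,reliability,0.072,own_ebv,
0.1,5000,,pa,,90.0,reliability,0.0735,own_ebv,
0.1,5000,,own_ebv,,100.0,reliability,0.0769,own_ebv,
0.1,10000,,own_ebv,,70.0,reliability,0.1279,pa,
0.1,10000,,own_ebv,,80.0,reliability,0.1306,pa,
0.1,10000,,own_ebv,,90.0,reliability,0.1344,pa,
0.1,10000,,pa,,100.0,reliability,0.1429,pa,
0.1,10000,,pa,,70.0,reliability,0.1325,own_ebv,
0.1,10000,,pa,,80.0,reliability,0.1343,own_ebv,
0.1,10000,,pa,,90.0,reliability,0.137,own_ebv,
0.1,10000,,own_ebv,,100.0,reliability,0.1429,own_ebv,
0.1,20000,,own_ebv,,70.0,reliability,0.2269,pa,printed value differs from recomputation by one unit in the last decimal
0.1,20000,,own_ebv,,80.0,reliability,0.2311,pa,
0.1,20000,,own_ebv,,90.0,reliability,0.237,pa,
0.1,20000,,pa,,100.0,reliability,0.25,pa,
0.1,20000,,pa,,70.0,reliability,0.2339,own_ebv,
0.1,20000,,pa,,80.0,reliability,0.2368,own_ebv,
0.1,20000,,pa,,90.0,reliability,0.241,own_ebv,
0.1,20000,,own_ebv,,100.0,reliability,0.25,own_ebv,
0.1,40000,,own_ebv,,70.0,reliability,0.3698,pa,
0.1,40000,,own_ebv,,80.0,reliability,0.3754,pa,
0.1,40000,,own_ebv,,90.0,reliability,0.3832,pa,
0.1,40000,,pa,,100.0,reliability,0.4,pa,
0.1,40000,,pa,,70.0,reliability,0.3792,own_ebv,
0.1,40000,,pa,,80.0,reliability,0.383,own_ebv,
0.1,40000,,pa,,90.0,reliability,0.3883,own_ebv,
0.1,40000,,own_ebv,,100.0,reliability,0.4,own_ebv,
0.3,5000,,own_ebv,,70.0,reliability,0.162,pa,
0.3,5000,,own_ebv,,80.0,reliability,0.169,pa,
0.3,5000,,own_ebv,,90.0,reliability,0.1789,pa,
0.3,5000,,pa,,100.0,reliability,0.2,pa,
0.3,5000,,pa,,70.0,reliability,0.177,own_ebv,
0.3,5000,,pa,,80.0,reliability,0.1812,own_ebv,
0.3,5000,,pa,,90.0,reliability,0.1871,own_ebv,
0.3,5000,,own_ebv,,100.0,reliability,0.2,own_ebv,
0.3,10000,,own_ebv,,70.0,reliability,0.2788,pa,
0.3,10000,,own_ebv,,80.0,reliability,0.2891,pa,
0.3,10000,,own_ebv,,90.0,reliability,0.3034,pa,
0.3,10000,,pa,,100.0,reliability,0.3333,pa,
0.3,10000,,pa,,70.0,reliability,0.3008,own_ebv,
0.3,10000,,pa,,80.0,reliability,0.3068,own_ebv,
0.3,10000,,pa,,90.0,reliability,0.3152,own_ebv,
0.3,10000,,own_ebv,,100.0,reliability,0.3333,own_ebv,
0.3,20000,,own_ebv,,70.0,reliability,0.4361,pa,printed value differs from recomputation by one unit in the last decimal
0.3,20000,,own_ebv,,80.0,reliability,0.4486,pa,
0.3,20000,,own_ebv,,90.0,reliability,0.4656,pa,
0.3,20000,,pa,,100.0,reliability,0.5,pa,
0.3,20000,,pa,,70.0,reliability,0.4625,own_ebv,printed value differs from recomputation by one unit in the last decimal
0.3,20000,,pa,,80.0,reliability,0.4695,own_ebv,
0.3,20000,,pa,,90.0,reliability,0.4793,own_ebv,
0.3,20000,,own_ebv,,100.0,reliability,0.5,own_ebv,
0.3,40000,,own_ebv,,70.0,reliability,0.6073,pa,
0.3,40000,,own_ebv,,80.0,reliability,0.6193,pa,
0.3,40000,,own_ebv,,90.0,reliability,0.6354,pa,
0.3,40000,,pa,,100.0,reliability,0.6667,pa,
0.3,40000,,pa,,70.0,reliability,0.6324,own_ebv,
0.3,40000,,pa,,80.0,reliability,0.639,own_ebv,
0.3,40000,,pa,,90.0,reliability,0.6481,own_ebv,
0.3,40000,,own_ebv,,100.0,reliability,0.6667,own_ebv,
0.5,5000,,own_ebv,,70.0,reliability,0.2243,pa,printed value differs from recomputation by one unit in the last decimal
0.5,5000,,own_ebv,,80.0,reliability,0.2376,pa,
0.5,5000,,own_ebv,,90.0,reliability,0.2561,pa,
0.5,5000,,pa,,100.0,reliability,0.2941,pa,
0.5,5000,,pa,,70.0,reliability,0.2559,own_ebv,
0.5,5000,,pa,,80.0,reliability,0.263,own_ebv,
0.5,5000,,pa,,90.0,reliability,0.2729,own_ebv,
0.5,5000,,own_ebv,,100.0,reliability,0.2941,own_ebv,
0.5,10000,,own_ebv,,70.0,reliability,0.3664,pa,printed value differs from recomputation by one unit in the last decimal
0.5,10000,,own_ebv,,80.0,reliability,0.384,pa,
0.5,10000,,own_ebv,,90.0,reliability,0.4077,pa,
0.5,10000,,pa,,100.0,reliability,0.4546,pa,printed value differs from recomputation by one unit in the last decimal
0.5,10000,,pa,,70.0,reliability,0.4075,own_ebv,
0.5,10000,,pa,,80.0,reliability,0.4164,own_ebv,printed value differs from recomputation by one unit in the last decimal
0.5,10000,,pa,,90.0,reliability,0.4288,own_ebv,
0.5,10000,,own_ebv,,100.0,reliability,0.4546,own_ebv,printed value differs from recomputation by one unit in the last decimal
0.5,20000,,own_ebv,,70.0,reliability,0.5363,pa,printed value differs from recomputation by one unit in the last decimal
0.5,20000,,own_ebv,,80.0,reliability,0.5549,pa,
0.5,20000,,own_ebv,,90.0,reliability,0.5793,pa,
0.5,20000,,pa,,100.0,reliability,0.625,pa,
0.5,20000,,pa,,70.0,reliability,0.5791,own_ebv,
0.5,20000,,pa,,80.0,reliability,0.588,own_ebv,
0.5,20000,,pa,,90.0,reliability,0.6002,own_ebv,
0.5,20000,,own_ebv,,100.0,reliability,0.625,own_ebv,
0.5,40000,,own_ebv,,70.0,reliability,0.6981,pa,
0.5,40000,,own_ebv,,80.0,reliability,0.7138,pa,
0.5,40000,,own_ebv,,90.0,reliability,0.7336,pa,
0.5,40000,,pa,,100.0,reliability,0.7692,pa,
0.5,40000,,pa,,70.0,reliability,0.7334,own_ebv,
0.5,40000,,pa,,80.0,reliability,0.7406,own_ebv,
0.5,40000,,pa,,90.0,reliability,0.7502,own_ebv,
0.5,40000,,own_ebv,,100.0,reliability,0.7692,own_ebv,
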