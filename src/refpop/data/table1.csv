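h2,n_ref,daughters,criterion,percent_m,percent_f,statistic,value,note
0.1,5000,50,pa,5.0,,ratio,0.8982,
0.1,5000,50,pa,30.0,,ratio,0.9137,
0.1,5000,50,pa,100.0,,reliability,0.3189,
0.1,5000,100,pa,5.0,,ratio,0.8817,
0.1,5000,100,pa,30.0,,ratio,0.9001,
0.1,5000,100,pa,100.0,,reliability,0.3748,
0.1,10000,50,pa,5.0,,ratio,0.9209,
0.1,10000,50,pa,30.0,,ratio,0.9332,
0.1,10000,50,pa,100.0,,reliability,0.4837,printed value differs from recomputation by one unit in the last decimal
0.1,10000,100,pa,5.0,,ratio,0.9111,
0.1,10000,100,pa,30.0,,ratio,0.9253,
0.1,10000,100,pa,100.0,,reliability,0.5453,
0.1,20000,50,pa,5.0,,ratio,0.9452,
0.1,20000,50,pa,30.0,,ratio,0.954,
0.1,20000,50,pa,100.0,,reliability,0.6519,
0.1,20000,100,pa,5.0,,ratio,0.9406,
0.1,20000,100,pa,30.0,,ratio,0.9503,
0.1,20000,100,pa,100.0,,reliability,0.7057,
0.1,40000,50,pa,5.0,,ratio,0.9661,
0.1,40000,50,pa,30.0,,ratio,0.9716,
0.1,40000,50,pa,100.0,,reliability,0.7893,
0.1,40000,100,pa,5.0,,ratio,0.9643,
0.1,40000,100,pa,30.0,,ratio,0.9703,
0.1,40000,100,pa,100.0,,reliability,0.8275,
0.3,5000,50,pa,5.0,,ratio,0.8426,
0.3,5000,50,pa,30.0,,ratio,0.8677,
0.3,5000,50,pa,100.0,,reliability,0.4006,
0.3,5000,100,pa,5.0,,ratio,0.8346,
0.3,5000,100,pa,30.0,,ratio,0.8613,
0.3,5000,100,pa,100.0,,reliability,0.4259,
0.3,10000,50,pa,5.0,,ratio,0.8823,
0.3,10000,50,pa,30.0,,ratio,0.9018,
0.3,10000,50,pa,100.0,,reliability,0.5721,
0.3,10000,100,pa,5.0,,ratio,0.878,
0.3,10000,100,pa,30.0,,ratio,0.8986,
0.3,10000,100,pa,100.0,,reliability,0.5974,
0.3,20000,50,pa,5.0,,ratio,0.9218,
0.3,20000,50,pa,30.0,,ratio,0.9352,
0.3,20000,50,pa,100.0,,reliability,0.7278,
0.3,20000,100,pa,5.0,,ratio,0.92,
0.3,20000,100,pa,30.0,,ratio,0.934,
0.3,20000,100,pa,100.0,,reliability,0.7479,
0.3,40000,50,pa,5.0,,ratio,0.9532,
0.3,40000,50,pa,30.0,,ratio,0.9615,
0.3,40000,50,pa,100.0,,reliability,0.8425,
0.3,40000,100,pa,5.0,,ratio,0.9526,
0.3,40000,100,pa,30.0,,ratio,0.9611,
0.3,40000,100,pa,100.0,,reliability,0.8558,
0.5,5000,50,pa,5.0,,ratio,0.8039,
0.5,5000,50,pa,30.0,,ratio,0.8361,
0.5,5000,50,pa,100.0,,reliability,0.4223,
0.5,5000,100,pa,5.0,,ratio,0.7989,
0.5,5000,100,pa,30.0,,ratio,0.8322,
0.5,5000,100,pa,100.0,,reliability,0.4378,
0.5,10000,50,pa,5.0,,ratio,0.8536,
0.5,10000,50,pa,30.0,,ratio,0.8789,printed value differs from recomputation by one unit in the last decimal
0.5,10000,50,pa,100.0,,reliability,0.5938,
0.5,10000,100,pa,5.0,,ratio,0.851,
0.5,10000,100,pa,30.0,,ratio,0.877,
0.5,10000,100,pa,100.0,,reliability,0.609,
0.5,20000,50,pa,5.0,,ratio,0.9028,
0.5,20000,50,pa,30.0,,ratio,0.9204,
0.5,20000,50,pa,100.0,,reliability,0.7452,
0.5,20000,100,pa,5.0,,ratio,0.9019,
0.5,20000,100,pa,30.0,,ratio,0.9198,
0.5,20000,100,pa,100.0,,reliability,0.757,
0.5,40000,50,pa,5.0,,ratio,0.9419,
0.5,40000,50,pa,30.0,,ratio,0.9528,
0.5,40000,50,pa,100.0,,reliability,0.854,
0.5,40000,100,pa,5.0,,ratio,0.9417,
0.5,40000,100,pa,30.0,,ratio,0.9527,
0.5,40000,100,pa,100.0,,reliability,0.8617,
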