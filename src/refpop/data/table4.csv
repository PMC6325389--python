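h2,n_ref,daughters,criterion,percent_m,percent_f,statistic,value,note
0.1,5000,50,pa,5.0,,bias,0.898,
0.1,5000,50,pa,30.0,,bias,0.914,
0.1,5000,100,pa,5.0,,bias,0.882,
0.1,5000,100,pa,30.0,,bias,0.9,
0.1,10000,50,pa,5.0,,bias,0.921,
0.1,10000,50,pa,30.0,,bias,0.933,
0.1,10000,100,pa,5.0,,bias,0.911,
0.1,10000,100,pa,30.0,,bias,0.925,
0.1,20000,50,pa,5.0,,bias,0.945,
0.1,20000,50,pa,30.0,,bias,0.954,
0.1,20000,100,pa,5.0,,bias,0.941,
0.1,20000,100,pa,30.0,,bias,0.95,
0.1,40000,50,pa,5.0,,bias,0.966,
0.1,40000,50,pa,30.0,,bias,0.972,
0.1,40000,100,pa,5.0,,bias,0.964,
0.1,40000,100,pa,30.0,,bias,0.97,
0.3,5000,50,pa,5.0,,bias,0.843,
0.3,5000,50,pa,30.0,,bias,0.868,
0.3,5000,100,pa,5.0,,bias,0.835,
0.3,5000,100,pa,30.0,,bias,0.861,
0.3,10000,50,pa,5.0,,bias,0.882,
0.3,10000,50,pa,30.0,,bias,0.902,
0.3,10000,100,pa,5.0,,bias,0.878,
0.3,10000,100,pa,30.0,,bias,0.899,
0.3,20000,50,pa,5.0,,bias,0.922,
0.3,20000,50,pa,30.0,,bias,0.935,
0.3,20000,100,pa,5.0,,bias,0.92,
0.3,20000,100,pa,30.0,,bias,0.934,
0.3,40000,50,pa,5.0,,bias,0.953,
0.3,40000,50,pa,30.0,,bias,0.961,
0.3,40000,100,pa,5.0,,bias,0.953,
0.3,40000,100,pa,30.0,,bias,0.961,
0.5,5000,50,pa,5.0,,bias,0.804,
0.5,5000,50,pa,30.0,,bias,0.836,
0.5,5000,100,pa,5.0,,bias,0.799,
0.5,5000,100,pa,30.0,,bias,0.832,
0.5,10000,50,pa,5.0,,bias,0.854,
0.5,10000,50,pa,30.0,,bias,0.879,
0.5,10000,100,pa,5.0,,bias,0.851,
0.5,10000,100,pa,30.0,,bias,0.877,
0.5,20000,50,pa,5.0,,bias,0.903,
0.5,20000,50,pa,30.0,,bias,0.92,
0.5,20000,100,pa,5.0,,bias,0.902,
0.5,20000,100,pa,30.0,,bias,0.92,
0.5,40000,50,pa,5.0,,bias,0.942,
0.5,40000,50,pa,30.0,,bias,0.953,
0.5,40000,100,pa,5.0,,bias,0.942,
0.5,40000,100,pa,30.0,,bias,0.953,
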