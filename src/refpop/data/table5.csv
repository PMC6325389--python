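h2,n_ref,daughters,criterion,percent_m,percent_f,statistic,value,note
0.1,5000,,own_ebv,,70.0,bias,0.888,
0.1,5000,,own_ebv,,90.0,bias,0.937,
0.1,5000,,pa,,70.0,bias,0.922,
0.1,5000,,pa,,90.0,bias,0.956,
0.1,10000,,own_ebv,,70.0,bias,0.896,printed value differs from recomputation by one unit in the last decimal
0.1,10000,,own_ebv,,90.0,bias,0.941,
0.1,10000,,pa,,70.0,bias,0.927,
0.1,10000,,pa,,90.0,bias,0.959,
0.1,20000,,own_ebv,,70.0,bias,0.907,
0.1,20000,,own_ebv,,90.0,bias,0.948,
0.1,20000,,pa,,70.0,bias,0.936,
0.1,20000,,pa,,90.0,bias,0.964,
0.1,40000,,own_ebv,,70.0,bias,0.925,printed value differs from recomputation by one unit in the last decimal
0.1,40000,,own_ebv,,90.0,bias,0.958,
0.1,40000,,pa,,70.0,bias,0.948,
0.1,40000,,pa,,90.0,bias,0.971,
0.3,5000,,own_ebv,,70.0,bias,0.81,
0.3,5000,,own_ebv,,90.0,bias,0.894,
0.3,5000,,pa,,70.0,bias,0.885,
0.3,5000,,pa,,90.0,bias,0.935,printed value differs from recomputation by one unit in the last decimal
0.3,10000,,own_ebv,,70.0,bias,0.837,printed value differs from recomputation by one unit in the last decimal
0.3,10000,,own_ebv,,90.0,bias,0.91,
0.3,10000,,pa,,70.0,bias,0.902,
0.3,10000,,pa,,90.0,bias,0.946,
0.3,20000,,own_ebv,,70.0,bias,0.872,
0.3,20000,,own_ebv,,90.0,bias,0.931,
0.3,20000,,pa,,70.0,bias,0.925,
0.3,20000,,pa,,90.0,bias,0.959,
0.3,40000,,own_ebv,,70.0,bias,0.911,
0.3,40000,,own_ebv,,90.0,bias,0.953,
0.3,40000,,pa,,70.0,bias,0.949,
0.3,40000,,pa,,90.0,bias,0.972,
0.5,5000,,own_ebv,,70.0,bias,0.762,
0.5,5000,,own_ebv,,90.0,bias,0.871,
0.5,5000,,pa,,70.0,bias,0.87,
0.5,5000,,pa,,90.0,bias,0.928,
0.5,10000,,own_ebv,,70.0,bias,0.806,
0.5,10000,,own_ebv,,90.0,bias,0.897,
0.5,10000,,pa,,70.0,bias,0.897,
0.5,10000,,pa,,90.0,bias,0.943,
0.5,20000,,own_ebv,,70.0,bias,0.858,
0.5,20000,,own_ebv,,90.0,bias,0.927,
0.5,20000,,pa,,70.0,bias,0.927,printed value differs from recomputation by one unit in the last decimal
0.5,20000,,pa,,90.0,bias,0.96,
0.5,40000,,own_ebv,,70.0,bias,0.908,
0.5,40000,,own_ebv,,90.0,bias,0.954,
0.5,40000,,pa,,70.0,bias,0.953,
0.5,40000,,pa,,90.0,bias,0.975,
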