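T_K,P_bar,rho_kg_m3,y2,S_gL,sd,U
308,120,769,1.25e-06,0.0106,5e-08,5.8e-07
308,150,817,1.73e-06,0.0155,7e-08,7.8e-07
308,180,849,1.92e-06,0.0180,2e-08,8.6e-07
308,210,875,2.35e-06,0.0226,8e-08,1.04e-06
308,240,896,2.97e-06,0.0292,1.1e-07,1.31e-06
308,270,914,3.13e-06,0.0315,1e-07,1.38e-06
318,120,661,1.01e-06,0.0072,3e-08,4.6e-07
318,150,744,1.21e-06,0.0098,4e-08,5.4e-07
318,180,791,1.43e-06,0.0124,2e-08,6.4e-07
318,210,824,3.17e-06,0.0287,5e-08,1.41e-06
318,240,851,3.42e-06,0.0319,2e-08,1.51e-06
318,270,872,3.89e-06,0.0372,3e-08,1.71e-06
328,120,509,6.4e-07,0.0036,2e-08,3.0e-07
328,150,656,9.8e-07,0.0070,4e-08,4.4e-07
328,180,725,1.26e-06,0.0100,6e-08,5.6e-07
328,210,769,3.92e-06,0.0331,3e-08,1.74e-06
328,240,802,4.21e-06,0.0371,7e-08,1.86e-06
328,270,829,4.31e-06,0.0392,6e-08,1.91e-06
338,120,388,3.1e-07,0.0013,1e-08,1.4e-07
338,150,557,6.2e-07,0.0037,3e-08,2.8e-07
338,180,652,1.02e-06,0.0072,1e-08,4.4e-07
338,210,710,4.43e-06,0.0346,1.2e-07,1.97e-06
338,240,751,4.97e-06,0.0410,9e-08,2.20e-06
338,270,783,6.44e-06,0.0553,6e-08,2.84e-06
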