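variety,model,mu,mu_se,tb,tb_se,tm,tm_se,a,a_se,aic,r2,msc,rmse
VE 201,briere1,,,8.9826,0.0011,40.1123,0.6633,0.0003,0.0001,-74.3393,0.9389,-0.8117,0.0014
VE 203,briere1,,,10.1398,0.0008,39.0562,0.1416,0.0003,0.00002,-68.7885,0.8794,-0.8737,0.0020
VE 206,briere1,,,9.515,0.1002,38.4895,0.1000,0.0003,0.00002,-71.7878,0.9010,-0.8500,0.0017
VE 208,briere1,,,8.5664,0.1008,38.587,0.2510,0.0003,0.0001,-70.7438,0.8763,-0.8719,0.0018
VE 210,briere1,,,9.6988,0.0310,39.1233,0.0523,0.0003,0.00001,-70.3806,0.8848,-0.8690,0.0018
VE 212,briere1,,,9.0336,0.0608,37.2379,0.1154,0.0003,0.00002,-72.3643,0.9242,-0.8238,0.0016
VE 218,briere1,,,8.1142,0.1004,40.0585,0.0001,0.0029,0.00004,-70.9964,0.9020,-0.8597,0.0017
VE 220,briere2,1.0307,0.000001,10.0339,0.000001,40.4344,0.0001,0.00004,0.000001,-65.2251,0.8765,-1.1314,0.0022
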