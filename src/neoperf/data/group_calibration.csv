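group,signal,quantity,mean,sd,basis
I,HbT,index_i,0.6795,0.0278,reported
I,HbT,index_ii,0.6409,0.0289,reported
I,HbT,index_iii,0.6680,0.0300,reported
I,HbT,index_vi,0.8399,0.3756,reported
II,HbT,index_i,0.6761,0.0290,assumed
II,HbT,index_ii,0.6361,0.0315,reported
II,HbT,index_iii,0.6695,0.0276,reported
II,HbT,index_vi,0.9000,0.3800,assumed
III,HbT,index_i,0.6546,0.0275,reported
III,HbT,index_ii,0.6108,0.0293,reported
III,HbT,index_iii,0.6475,0.0295,reported
III,HbT,index_vi,1.1222,0.6491,reported
IV,HbT,index_i,0.6454,0.0456,reported
IV,HbT,index_ii,0.6060,0.0455,reported
IV,HbT,index_iii,0.6416,0.0455,reported
IV,HbT,index_vi,1.2393,0.4759,reported
I,StO2,index_i,52.8500,0.9000,assumed
I,StO2,index_ii,52.3000,0.9000,assumed
I,StO2,index_iii,52.6000,0.9000,assumed
I,StO2,index_vii,9.2185,12.0192,reported
II,StO2,index_i,52.9000,0.9000,assumed
II,StO2,index_ii,52.4154,0.9043,reported
II,StO2,index_iii,52.6500,0.9000,assumed
II,StO2,index_vii,8.5000,11.0000,assumed
III,StO2,index_i,52.4000,0.9000,assumed
III,StO2,index_ii,51.9000,0.9000,assumed
III,StO2,index_iii,52.2000,0.9000,assumed
III,StO2,index_vii,2.9323,9.5071,reported
IV,StO2,index_i,52.1000,0.9000,assumed
IV,StO2,index_ii,51.5932,0.8693,reported
IV,StO2,index_iii,51.9000,0.9000,assumed
IV,StO2,index_vii,2.8658,10.8890,reported
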