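Age (Years + Months)   Boys    Girls
--------------------------------------
       0+3             2.315   2.153
       0+4             2.165   2.052
       0+5             2.131   2.024
       0+6             2.096   1.995
       0+7             2.040   1.944
       0+8             2.006   1.916
       0+9             1.971   1.887
      0+10             1.968   1.839
      0+11             1.934   1.839
       1+0             1.899   1.810
       1+1             1.888   1.799
       1+2             1.877   1.788
       1+3             1.865   1.777
       1+4             1.854   1.765
       1+5             1.843   1.754
       1+6             1.832   1.743
       1+7             1.820   1.732
       1+8             1.809   1.721
       1+9             1.798   1.710
      1+10             1.787   1.698
      1+11             1.775   1.687
       2+0             1.764   1.676
       2+1             1.758   1.671
       2+2             1.753   1.666
       2+3             1.747   1.662
       2+4             1.741   1.657
       2+5             1.736   1.652
       2+6             1.730   1.647
       2+7             1.724   1.642
       2+8             1.719   1.637
       2+9             1.713   1.633
      2+10             1.707   1.628
      2+11             1.702   1.623
       3+0             1.696   1.618
       3+1             1.688   1.611
       3+2             1.681   1.603
       3+3             1.673   1.596
       3+4             1.666   1.589
       3+5             1.658   1.581
       3+6             1.651   1.574
       3+7             1.643   1.567
       3+8             1.635   1.559
       3+9             1.628   1.552
      3+10             1.620   1.545
      3+11             1.613   1.537
       4+0             1.605   1.530
       4+1             1.598   1.523
       4+2             1.591   1.516
       4+3             1.585   1.508
       4+4             1.578   1.501
       4+5             1.571   1.494
       4+6             1.564   1.487
       4+7             1.557   1.479
       4+8             1.550   1.472
       4+9             1.544   1.465
      4+10             1.537   1.458
      4+11             1.530   1.450
       5+0             1.523   1.443
       5+1             1.517   1.437
       5+2             1.512   1.431
       5+3             1.506   1.425
       5+4             1.500   1.419
       5+5             1.494   1.413
       5+6             1.489   1.408
       5+7             1.483   1.402
       5+8             1.477   1.396
       5+9             1.471   1.390
      5+10             1.466   1.384
      5+11             1.460   1.378
       6+0             1.454   1.372
       6+1             1.449   1.368
       6+2             1.443   1.364
       6+3             1.438   1.360
       6+4             1.432   1.356
       6+5             1.427   1.352
       6+6             1.422   1.348
       6+7             1.416   1.344
       6+8             1.411   1.340
       6+9             1.405   1.336
      6+10             1.400   1.332
      6+11             1.394   1.328
       7+0             1.389   1.324
       7+1             1.385   1.319
       7+2             1.381   1.315
       7+3             1.376   1.310
       7+4             1.372   1.305
       7+5             1.368   1.300
       7+6             1.364   1.296
       7+7             1.359   1.291
       7+8             1.355   1.286
       7+9             1.351   1.281
      7+10             1.347   1.277
      7+11             1.342   1.272
       8+0             1.338   1.267
       8+1             1.334   1.263
       8+2             1.331   1.258
       8+3             1.327   1.254
       8+4             1.323   1.250
       8+5             1.319   1.245
       8+6             1.316   1.241
       8+7             1.312   1.237
       8+8             1.308   1.232
       8+9             1.304   1.228
      8+10             1.301   1.224
      8+11             1.297   1.219
       9+0             1.293   1.215
       9+1             1.291   1.212
       9+2             1.288   1.209
       9+3             1.286   1.206
       9+4             1.283   1.203
       9+5             1.281   1.200
       9+6             1.278   1.197
       9+7             1.276   1.193
       9+8             1.273   1.190
       9+9             1.271   1.187
      9+10             1.268   1.184
      9+11             1.266   1.181
      10+0             1.263   1.178
      10+1             1.260   1.175
      10+2             1.258   1.172
      10+3             1.255   1.169
      10+4             1.252   1.166
      10+5             1.249   1.163
      10+6             1.247   1.161
      10+7             1.244   1.158
      10+8             1.241   1.155
      10+9             1.238   1.152
     10+10             1.236   1.149
     10+11             1.233   1.146
      11+0             1.230   1.143
      11+1             1.227   1.140
      11+2             1.224   1.136
      11+3             1.221   1.133
      11+4             1.217   1.129
      11+5             1.214   1.126
      11+6             1.211   1.122
      11+7             1.208   1.119
      11+8             1.205   1.115
      11+9             1.202   1.112
     11+10             1.198   1.108
     11+11             1.195   1.105
      12+0             1.192   1.101
      12+1             1.189   1.098
      12+2             1.185   1.094
      12+3             1.182   1.091
      12+4             1.178   1.088
      12+5             1.175   1.084
      12+6             1.171   1.081
      12+7             1.168   1.078
      12+8             1.164   1.074
      12+9             1.161   1.071
     12+10             1.157   1.068
     12+11             1.154   1.064
      13+0             1.150   1.061
      13+1             1.146   1.058
      13+2             1.142   1.056
      13+3             1.138   1.053
      13+4             1.133   1.051
      13+5             1.129   1.048
      13+6             1.125   1.046
      13+7             1.121   1.043
      13+8             1.117   1.040
      13+9             1.113   1.038
     13+10             1.108   1.035
     13+11             1.104   1.033
      14+0             1.100   1.030
      14+1             1.097   1.029
      14+2             1.093   1.027
      14+3             1.090   1.026
      14+4             1.086   1.024
      14+5             1.083   1.023
      14+6             1.080   1.021
      14+7             1.076   1.020
      14+8             1.073   1.018
      14+9             1.069   1.017
     14+10             1.066   1.015
     14+11             1.062   1.014
      15+0             1.059   1.012
      15+1             1.056   1.011
      15+2             1.054   1.010
      15+3             1.051   1.009
      15+4             1.048   1.008
      15+5             1.045   1.007
      15+6             1.043   1.006
      15+7             1.040   1.005
      15+8             1.037   1.004
      15+9             1.034   1.003
     15+10             1.032   1.002
     15+11             1.029   1.001
      16+0             1.026   1.000
      16+1             1.025     -  
      16+2             1.023     -  
      16+3             1.022     -  
      16+4             1.021     -  
      16+5             1.019     -  
      16+6             1.018     -  
      16+7             1.017     -  
      16+8             1.015     -  
      16+9             1.014     -  
     16+10             1.013     -  
     16+11             1.011     -  
      17+0             1.010     -  
      17+1             1.009     -  
      17+2             1.008     -  
      17+3             1.008     -  
      17+4             1.007     -  
      17+5             1.006     -  
      17+6             1.005     -  
      17+7             1.004     -  
      17+8             1.003     -  
      17+9             1.003     -  
     17+10             1.002     -  
     17+11             1.001     -  
      18+0             1.000     -  
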