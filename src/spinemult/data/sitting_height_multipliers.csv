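sex,age_years,age_months,multiplier
male,0,3,2.315
male,0,4,2.165
male,0,5,2.131
male,0,6,2.096
male,0,7,2.040
male,0,8,2.006
male,0,9,1.971
male,0,10,1.968
male,0,11,1.934
male,1,0,1.899
male,1,1,1.888
male,1,2,1.877
male,1,3,1.865
male,1,4,1.854
male,1,5,1.843
male,1,6,1.832
male,1,7,1.820
male,1,8,1.809
male,1,9,1.798
male,1,10,1.787
male,1,11,1.775
male,2,0,1.764
male,2,1,1.758
male,2,2,1.753
male,2,3,1.747
male,2,4,1.741
male,2,5,1.736
male,2,6,1.730
male,2,7,1.724
male,2,8,1.719
male,2,9,1.713
male,2,10,1.707
male,2,11,1.702
male,3,0,1.696
male,3,1,1.688
male,3,2,1.681
male,3,3,1.673
male,3,4,1.666
male,3,5,1.658
male,3,6,1.651
male,3,7,1.643
male,3,8,1.635
male,3,9,1.628
male,3,10,1.620
male,3,11,1.613
male,4,0,1.605
male,4,1,1.598
male,4,2,1.591
male,4,3,1.585
male,4,4,1.578
male,4,5,1.571
male,4,6,1.564
male,4,7,1.557
male,4,8,1.550
male,4,9,1.544
male,4,10,1.537
male,4,11,1.530
male,5,0,1.523
male,5,1,1.517
male,5,2,1.512
male,5,3,1.506
male,5,4,1.500
male,5,5,1.494
male,5,6,1.489
male,5,7,1.483
male,5,8,1.477
male,5,9,1.471
male,5,10,1.466
male,5,11,1.460
male,6,0,1.454
male,6,1,1.449
male,6,2,1.443
male,6,3,1.438
male,6,4,1.432
male,6,5,1.427
male,6,6,1.422
male,6,7,1.416
male,6,8,1.411
male,6,9,1.405
male,6,10,1.400
male,6,11,1.394
male,7,0,1.389
male,7,1,1.385
male,7,2,1.381
male,7,3,1.376
male,7,4,1.372
male,7,5,1.368
male,7,6,1.364
male,7,7,1.359
male,7,8,1.355
male,7,9,1.351
male,7,10,1.347
male,7,11,1.342
male,8,0,1.338
male,8,1,1.334
male,8,2,1.331
male,8,3,1.327
male,8,4,1.323
male,8,5,1.319
male,8,6,1.316
male,8,7,1.312
male,8,8,1.308
male,8,9,1.304
male,8,10,1.301
male,8,11,1.297
male,9,0,1.293
male,9,1,1.291
male,9,2,1.288
male,9,3,1.286
male,9,4,1.283
male,9,5,1.281
male,9,6,1.278
male,9,7,1.276
male,9,8,1.273
male,9,9,1.271
male,9,10,1.268
male,9,11,1.266
male,10,0,1.263
male,10,1,1.260
male,10,2,1.258
male,10,3,1.255
male,10,4,1.252
male,10,5,1.249
male,10,6,1.247
male,10,7,1.244
male,10,8,1.241
male,10,9,1.238
male,10,10,1.236
male,10,11,1.233
male,11,0,1.230
male,11,1,1.227
male,11,2,1.224
male,11,3,1.221
male,11,4,1.217
male,11,5,1.214
male,11,6,1.211
male,11,7,1.208
male,11,8,1.205
male,11,9,1.202
male,11,10,1.198
male,11,11,1.195
male,12,0,1.192
male,12,1,1.189
male,12,2,1.185
male,12,3,1.182
male,12,4,1.178
male,12,5,1.175
male,12,6,1.171
male,12,7,1.168
male,12,8,1.164
male,12,9,1.161
male,12,10,1.157
male,12,11,1.154
male,13,0,1.150
male,13,1,1.146
male,13,2,1.142
male,13,3,1.138
male,13,4,1.133
male,13,5,1.129
male,13,6,1.125
male,13,7,1.121
male,13,8,1.117
male,13,9,1.113
male,13,10,1.108
male,13,11,1.104
male,14,0,1.100
male,14,1,1.097
male,14,2,1.093
male,14,3,1.090
male,14,4,1.086
male,14,5,1.083
male,14,6,1.080
male,14,7,1.076
male,14,8,1.073
male,14,9,1.069
male,14,10,1.066
male,14,11,1.062
male,15,0,1.059
male,15,1,1.056
male,15,2,1.054
male,15,3,1.051
male,15,4,1.048
male,15,5,1.045
male,15,6,1.043
male,15,7,1.040
male,15,8,1.037
male,15,9,1.034
male,15,10,1.032
male,15,11,1.029
male,16,0,1.026
male,16,1,1.025
male,16,2,1.023
male,16,3,1.022
male,16,4,1.021
male,16,5,1.019
male,16,6,1.018
male,16,7,1.017
male,16,8,1.015
male,16,9,1.014
male,16,10,1.013
male,16,11,1.011
male,17,0,1.010
male,17,1,1.009
male,17,2,1.008
male,17,3,1.008
male,17,4,1.007
male,17,5,1.006
male,17,6,1.005
male,17,7,1.004
male,17,8,1.003
male,17,9,1.003
male,17,10,1.002
male,17,11,1.001
male,18,0,1.000
female,0,3,2.153
female,0,4,2.052
female,0,5,2.024
female,0,6,1.995
female,0,7,1.944
female,0,8,1.916
female,0,9,1.887
female,0,10,1.839
female,0,11,1.839
female,1,0,1.810
female,1,1,1.799
female,1,2,1.788
female,1,3,1.777
female,1,4,1.765
female,1,5,1.754
female,1,6,1.743
female,1,7,1.732
female,1,8,1.721
female,1,9,1.710
female,1,10,1.698
female,1,11,1.687
female,2,0,1.676
female,2,1,1.671
female,2,2,1.666
female,2,3,1.662
female,2,4,1.657
female,2,5,1.652
female,2,6,1.647
female,2,7,1.642
female,2,8,1.637
female,2,9,1.633
female,2,10,1.628
female,2,11,1.623
female,3,0,1.618
female,3,1,1.611
female,3,2,1.603
female,3,3,1.596
female,3,4,1.589
female,3,5,1.581
female,3,6,1.574
female,3,7,1.567
female,3,8,1.559
female,3,9,1.552
female,3,10,1.545
female,3,11,1.537
female,4,0,1.530
female,4,1,1.523
female,4,2,1.516
female,4,3,1.508
female,4,4,1.501
female,4,5,1.494
female,4,6,1.487
female,4,7,1.479
female,4,8,1.472
female,4,9,1.465
female,4,10,1.458
female,4,11,1.450
female,5,0,1.443
female,5,1,1.437
female,5,2,1.431
female,5,3,1.425
female,5,4,1.419
female,5,5,1.413
female,5,6,1.408
female,5,7,1.402
female,5,8,1.396
female,5,9,1.390
female,5,10,1.384
female,5,11,1.378
female,6,0,1.372
female,6,1,1.368
female,6,2,1.364
female,6,3,1.360
female,6,4,1.356
female,6,5,1.352
female,6,6,1.348
female,6,7,1.344
female,6,8,1.340
female,6,9,1.336
female,6,10,1.332
female,6,11,1.328
female,7,0,1.324
female,7,1,1.319
female,7,2,1.315
female,7,3,1.310
female,7,4,1.305
female,7,5,1.300
female,7,6,1.296
female,7,7,1.291
female,7,8,1.286
female,7,9,1.281
female,7,10,1.277
female,7,11,1.272
female,8,0,1.267
female,8,1,1.263
female,8,2,1.258
female,8,3,1.254
female,8,4,1.250
female,8,5,1.245
female,8,6,1.241
female,8,7,1.237
female,8,8,1.232
female,8,9,1.228
female,8,10,1.224
female,8,11,1.219
female,9,0,1.215
female,9,1,1.212
female,9,2,1.209
female,9,3,1.206
female,9,4,1.203
female,9,5,1.200
female,9,6,1.197
female,9,7,1.193
female,9,8,1.190
female,9,9,1.187
female,9,10,1.184
female,9,11,1.181
female,10,0,1.178
female,10,1,1.175
female,10,2,1.172
female,10,3,1.169
female,10,4,1.166
female,10,5,1.163
female,10,6,1.161
female,10,7,1.158
female,10,8,1.155
female,10,9,1.152
female,10,10,1.149
female,10,11,1.146
female,11,0,1.143
female,11,1,1.140
female,11,2,1.136
female,11,3,1.133
female,11,4,1.129
female,11,5,1.126
female,11,6,1.122
female,11,7,1.119
female,11,8,1.115
female,11,9,1.112
female,11,10,1.108
female,11,11,1.105
female,12,0,1.101
female,12,1,1.098
female,12,2,1.094
female,12,3,1.091
female,12,4,1.088
female,12,5,1.084
female,12,6,1.081
female,12,7,1.078
female,12,8,1.074
female,12,9,1.071
female,12,10,1.068
female,12,11,1.064
female,13,0,1.061
female,13,1,1.058
female,13,2,1.056
female,13,3,1.053
female,13,4,1.051
female,13,5,1.048
female,13,6,1.046
female,13,7,1.043
female,13,8,1.040
female,13,9,1.038
female,13,10,1.035
female,13,11,1.033
female,14,0,1.030
female,14,1,1.029
female,14,2,1.027
female,14,3,1.026
female,14,4,1.024
female,14,5,1.023
female,14,6,1.021
female,14,7,1.020
female,14,8,1.018
female,14,9,1.017
female,14,10,1.015
female,14,11,1.014
female,15,0,1.012
female,15,1,1.011
female,15,2,1.010
female,15,3,1.009
female,15,4,1.008
female,15,5,1.007
female,15,6,1.006
female,15,7,1.005
female,15,8,1.004
female,15,9,1.003
female,15,10,1.002
female,15,11,1.001
female,16,0,1.000
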