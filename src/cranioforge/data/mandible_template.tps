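LM=15
1.792000 0.000000
1.818138 0.505930
1.154557 0.801416
0.510363 0.981710
-0.173039 1.028975
-0.708939 0.767448
-1.071591 0.486598
-1.340825 0.178126
-1.485374 -0.197329
-1.613263 -0.732565
-1.083061 -1.172448
-0.173855 -1.033827
0.382491 -0.735742
0.778787 -0.540582
1.213611 -0.337709
CURVES=3
POINTS=20
1.842472 0.057625
1.911877 0.187033
1.921538 0.320159
1.867722 0.447118
1.756750 0.559185
1.603165 0.651201
1.425611 0.722853
1.241772 0.778352
1.064046 0.824587
0.897306 0.868384
0.739351 0.913845
0.583677 0.960704
0.423399 1.004288
0.254813 1.037068
0.079301 1.051246
-0.097006 1.041438
-0.265530 1.006500
-0.418465 0.949900
-0.551591 0.878546
-0.665554 0.800562
POINTS=15
-0.760414 0.726661
-0.884600 0.627753
-1.006119 0.536002
-1.125180 0.443860
-1.230941 0.343717
-1.311864 0.233381
-1.367260 0.115590
-1.410568 -0.007412
-1.460535 -0.139142
-1.525304 -0.288766
-1.590292 -0.464261
-1.619318 -0.662842
-1.570242 -0.865443
-1.416903 -1.040254
-1.164506 -1.154746
POINTS=10
-0.947423 -1.188015
-0.502934 -1.144919
-0.118882 -1.009077
0.166705 -0.857270
0.383745 -0.735078
0.573267 -0.640791
0.752663 -0.553671
0.932499 -0.463706
1.140541 -0.368966
1.400758 -0.254768
ID=template
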