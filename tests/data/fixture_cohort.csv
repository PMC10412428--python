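patient_id,age,sex,fibrosis_stage,nas,gap_days,diabetes,bmi,ast,alt,platelets,albumin,mir34a,ykl40,a2m,hba1c,ha,piiinp,timp1,fpg
S01,57,female,1,4,2,False,30.3374,68.5102,33.6408,273.986,3.84829,0.39476,119.835,1.48464,5.1834,50.6035,13.7665,176.533,6.08731
S02,39,male,2,8,77,False,33.4798,82.0491,62.2452,325.55,3.93163,5.25435,596.009,2.21169,6.89485,84.6977,9.75076,336.131,5.92259
S03,55,female,2,5,5,True,32.8897,44.1372,23.66,176.796,3.69937,3.61436,39.3998,2.40258,5.827,63.8546,9.6255,257.885,7.92531
S04,42,male,3,4,42,True,32.9961,38.2838,87.984,163.105,3.98441,0.83947,340.349,1.60524,7.00885,134.845,14.1427,313.26,7.84295
S05,56,male,3,3,82,False,37.6143,56.9343,141.965,186.524,4.03746,1.61572,57.3652,1.10956,6.12392,47.8342,3.38117,154.591,5.36147
S06,61,female,1,1,85,True,26.5431,19.0773,46.0746,262.41,4.24158,2.58519,70.0593,2.18384,7.01572,129.626,24.0792,174.786,6.10914
S07,71,female,2,4,60,True,28.9249,34.5433,81.7596,371.895,4.57298,2.51128,277.895,2.03807,4.73571,92.3143,8.9925,341.534,8.55992
S08,58,male,2,2,83,False,38.1718,15.9807,17.7635,294.046,4.66794,0.701791,83.3193,2.38729,4.7951,101.553,16.0548,137.928,4.89296
S09,63,male,1,1,83,False,43.1713,39.3866,33.9732,233.039,5.03047,0.911253,89.0292,2.46048,5.50314,4.97087,3.25798,350.699,4.21488
S10,39,male,3,8,75,True,38.8798,46.1883,54.9371,139.823,4.66265,2.79586,147.316,2.64031,7.63143,44.7223,7.81267,433.311,6.49647
S11,45,female,1,2,77,False,35.5702,18.8583,63.2919,159.965,3.91497,1.45662,24.4223,2.01182,6.21661,45.2198,10.4899,280.578,5.34169
S12,45,male,1,3,45,False,28.1653,16.0961,35.8396,222.167,4.74508,1.32352,39.4127,3.62219,5.72731,37.8116,10.3295,209.596,4.1122
S13,48,male,3,8,57,False,36.4026,130.524,176.072,243.771,4.61397,1.4339,161.386,4.32705,6.27957,145.915,11.0743,381.422,7.07605
S14,68,male,2,5,26,True,35.48,25.0421,38.2232,135.676,4.15845,1.79502,92.2,3.20538,6.5366,118.175,9.62005,259.024,7.96304
S15,68,male,2,0,72,False,28.3838,26.0463,27.2719,253.631,3.91299,0.778252,58.321,1.34613,5.91197,17.9685,7.3642,307.208,9.57385
S16,61,male,4,5,40,False,26.8186,61.0019,29.0861,125.04,4.46472,0.860555,154.01,3.74178,5.61653,121.406,12.3912,412.103,6.34119
S17,54,male,0,3,86,False,33.4931,22.4166,31.7514,364.409,4.50234,0.432737,112.245,1.98383,4.1153,40.9043,6.56052,172.605,4.27895
S18,48,male,2,8,84,True,33.3799,55.1965,116.78,158.753,4.08348,4.46758,50.9245,4.69203,6.44846,91.726,8.87783,206.076,4.55217
S19,73,male,1,3,20,False,35.8133,23.1194,23.5996,267.63,4.58257,0.513051,20.6382,1.32668,7.3981,15.1971,9.51764,153.333,6.70613
S20,56,female,1,1,12,True,34.1082,25.2905,15.1577,200.19,4.00565,0.359361,45.4581,1.37328,5.24405,46.8251,9.93699,192.26,3.59625
S21,39,female,4,2,48,False,30.233,22.8889,38.1125,224.833,3.94233,0.383742,49.8598,2.07027,6.33047,52.5514,8.70336,330.822,4.22077
S22,43,female,2,6,62,False,32.1165,44.2421,50.8335,172.856,4.22761,0.462652,109.551,2.05644,7.26981,60.4143,7.56604,227.591,4.73697
S23,50,male,1,3,20,True,34.3978,22.4592,45.1025,137.553,3.98238,0.900776,35.4959,1.68444,6.21529,119.455,6.48615,236.817,6.31629
S24,72,female,3,5,89,True,33.9362,22.6194,58.69,229.081,4.75078,1.00322,163.133,2.61449,4.6052,27.276,13.3179,244.699,4.69757
S25,46,male,2,3,52,False,28.4077,36.3503,17.835,214.823,4.38441,1.01101,116.395,1.47492,6.79659,37.0086,7.38027,161.663,4.51985
S26,45,male,3,4,61,False,38.1318,33.8844,40.4052,237.27,4.60821,2.15236,133.09,2.16598,6.83459,68.2452,14.5983,379.499,5.67127
S27,62,male,4,4,58,True,40.7197,26.062,69.3672,79.2382,4.47359,1.85928,69.5523,1.98491,6.29695,91.9194,16.8402,324.905,5.34864
S28,47,male,1,3,71,True,29.53,22.2587,37.5892,313.268,4.68335,0.864319,20.7942,0.769888,5.98849,30.3228,7.02119,212.545,6.09554
S29,64,male,3,7,48,True,43.6641,108.931,31.5407,189.353,4.59017,1.16996,82.0556,1.52225,7.6529,257.822,7.3821,247.246,8.28793
S30,40,male,2,3,85,False,28.7977,38.1555,36.5901,325.75,4.58424,0.510301,83.6198,1.51376,5.34102,65.2932,10.4268,161.954,5.78234
S31,48,male,2,5,68,False,31.8988,32.2733,85.4218,269.755,4.3067,0.785827,35.6835,1.8136,6.17993,196.425,13.1314,177.854,4.49487
S32,69,male,1,5,74,False,20.2059,17.9212,52.8525,206.657,5.60179,1.27527,32.0842,2.00315,7.45171,97.2914,7.31268,173.758,5.87267
S33,58,male,3,4,70,False,39.301,77.033,122.095,337.934,4.26623,4.68937,426.784,3.38537,7.72342,54.1896,6.10017,178.952,5.80166
S34,32,male,2,8,6,False,42.6326,41.7184,68.2485,275.132,4.60186,2.14093,164.214,1.90523,5.75107,189.272,11.0798,380.785,5.9657
S35,60,male,1,1,69,False,35.9132,12.4491,15.1841,214.911,4.20251,0.430831,53.4239,2.44737,5.29819,61.1021,5.23555,254.965,5.78253
S36,68,male,4,3,13,True,32.3923,17.641,35.7975,150.796,4.81124,1.13792,90.5418,2.3602,5.50983,69.4431,5.11546,212.457,4.21723
S37,71,female,3,6,48,True,29.0232,58.3896,86.5492,216.108,5.03079,5.25351,327.952,1.74486,7.19936,56.3485,10.3449,359.629,6.36547
S38,52,male,1,4,18,False,36.0908,32.6703,52.116,248.875,4.19809,0.586382,94.2098,2.33532,4.72109,132.662,8.26128,183.865,5.31157
S39,35,male,1,2,85,False,39.2195,23.3016,11.746,244.006,4.54904,0.853828,56.1084,1.43744,5.62047,11.9424,4.98141,228.676,4.20643
S40,52,male,2,6,12,False,32.3534,24.3608,60.5134,206.737,4.4488,1.4802,119.243,2.50982,5.21147,150.668,15.4197,313.499,11.0516
S41,43,male,2,0,72,False,34.3441,29.7735,47.8431,198.497,4.37564,1.1717,31.5818,3.70463,5.09403,35.7515,5.36427,341.582,4.17772
S42,59,male,2,2,13,True,30.6755,21.72,34.3311,179.404,4.84069,1.06737,67.6295,2.02152,6.89713,63.474,11.8057,250.58,5.63186
S43,71,male,3,7,14,True,31.6943,98.3641,49.0327,191.274,4.5145,3.83801,76.2457,2.18515,6.44285,228.305,5.20932,281.469,3.64913
S44,45,male,2,6,90,False,30.6787,98.1988,92.4613,296.971,4.55058,3.39816,222.645,1.62599,6.77341,171.552,9.98761,312.996,5.00943
S45,42,male,3,6,56,True,45.2679,70.4435,44.3247,239.48,4.11883,0.91021,113.265,2.17512,4.5218,41.8752,9.51682,314.769,5.04454
S46,47,male,3,4,90,False,38.5303,75.5842,44.5905,133.685,4.15925,3.6071,106.293,1.49383,5.3203,79.9004,24.7317,363.829,4.14675
S47,56,female,4,5,89,False,22.3331,14.0195,68.9235,118.339,4.15085,1.47106,210.506,4.02111,5.13134,161.823,6.65148,164.641,6.85059
S48,62,male,3,1,76,False,25.7623,32.7079,45.6776,202.934,4.55642,0.518709,92.9757,1.60958,5.68373,30.2544,6.66347,330.651,4.23332
S49,53,male,3,6,7,False,32.8535,66.7214,105.796,291.074,4.23156,1.62911,162.284,3.83595,6.47562,28.8768,8.60071,292.485,5.61571
S50,47,male,1,5,51,False,28.3717,33.3183,60.729,292.984,4.72821,2.11823,172.072,3.50041,5.98779,18.5354,9.44451,217.033,5.47742
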