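# Synthetic SPR dissociation traces (stand-ins for figure-digitised
# sensorgrams): one-phase decays generated from the anchor kinetics in
# defaults.yaml with 1% Gaussian noise, seeds 100-103. Time in minutes.
time_min,response,label
0.0,98.842,PC9-WT
0.102,91.47,PC9-WT
0.2041,83.935,PC9-WT
0.3061,76.395,PC9-WT
0.4082,68.243,PC9-WT
0.5102,64.228,PC9-WT
0.6122,58.354,PC9-WT
0.7143,53.349,PC9-WT
0.8163,48.832,PC9-WT
0.9184,45.043,PC9-WT
1.0204,42.408,PC9-WT
1.1224,36.119,PC9-WT
1.2245,33.652,PC9-WT
1.3265,32.514,PC9-WT
1.4286,26.834,PC9-WT
1.5306,26.142,PC9-WT
1.6327,22.984,PC9-WT
1.7347,21.703,PC9-WT
1.8367,20.422,PC9-WT
1.9388,16.401,PC9-WT
2.0408,15.87,PC9-WT
2.1429,14.12,PC9-WT
2.2449,14.077,PC9-WT
2.3469,12.511,PC9-WT
2.449,13.707,PC9-WT
2.551,10.672,PC9-WT
2.6531,12.154,PC9-WT
2.7551,9.274,PC9-WT
2.8571,9.261,PC9-WT
2.9592,8.4,PC9-WT
3.0612,7.8,PC9-WT
3.1633,6.14,PC9-WT
3.2653,7.128,PC9-WT
3.3673,6.746,PC9-WT
3.4694,6.207,PC9-WT
3.5714,6.233,PC9-WT
3.6735,4.468,PC9-WT
3.7755,4.694,PC9-WT
3.8776,4.06,PC9-WT
3.9796,2.773,PC9-WT
4.0816,4.622,PC9-WT
4.1837,3.416,PC9-WT
4.2857,3.789,PC9-WT
4.3878,5.948,PC9-WT
4.4898,3.776,PC9-WT
4.5918,3.514,PC9-WT
4.6939,4.354,PC9-WT
4.7959,4.411,PC9-WT
4.898,4.873,PC9-WT
5.0,2.443,PC9-WT
0.0,99.21,PC9-TM
0.102,91.273,PC9-TM
0.2041,87.676,PC9-TM
0.3061,82.008,PC9-TM
0.4082,75.541,PC9-TM
0.5102,71.175,PC9-TM
0.6122,67.82,PC9-TM
0.7143,62.792,PC9-TM
0.8163,58.36,PC9-TM
0.9184,54.54,PC9-TM
1.0204,49.448,PC9-TM
1.1224,47.977,PC9-TM
1.2245,42.291,PC9-TM
1.3265,40.743,PC9-TM
1.4286,37.97,PC9-TM
1.5306,34.192,PC9-TM
1.6327,33.494,PC9-TM
1.7347,33.09,PC9-TM
1.8367,29.095,PC9-TM
1.9388,26.354,PC9-TM
2.0408,25.726,PC9-TM
2.1429,25.044,PC9-TM
2.2449,22.868,PC9-TM
2.3469,21.26,PC9-TM
2.449,18.539,PC9-TM
2.551,19.223,PC9-TM
2.6531,18.066,PC9-TM
2.7551,17.858,PC9-TM
2.8571,17.014,PC9-TM
2.9592,15.29,PC9-TM
3.0612,12.099,PC9-TM
3.1633,11.504,PC9-TM
3.2653,11.094,PC9-TM
3.3673,11.791,PC9-TM
3.4694,10.061,PC9-TM
3.5714,11.553,PC9-TM
3.6735,9.925,PC9-TM
3.7755,9.521,PC9-TM
3.8776,9.418,PC9-TM
3.9796,8.553,PC9-TM
4.0816,6.377,PC9-TM
4.1837,9.845,PC9-TM
4.2857,8.488,PC9-TM
4.3878,8.205,PC9-TM
4.4898,5.614,PC9-TM
4.5918,4.216,PC9-TM
4.6939,4.28,PC9-TM
4.7959,4.474,PC9-TM
4.898,6.169,PC9-TM
5.0,5.963,PC9-TM
0.0,100.626,PC9-F404D
0.102,83.428,PC9-F404D
0.2041,67.065,PC9-F404D
0.3061,52.772,PC9-F404D
0.4082,43.345,PC9-F404D
0.5102,36.782,PC9-F404D
0.6122,29.392,PC9-F404D
0.7143,25.383,PC9-F404D
0.8163,18.006,PC9-F404D
0.9184,18.629,PC9-F404D
1.0204,15.626,PC9-F404D
1.1224,10.048,PC9-F404D
1.2245,9.385,PC9-F404D
1.3265,7.609,PC9-F404D
1.4286,6.656,PC9-F404D
1.5306,7.06,PC9-F404D
1.6327,4.801,PC9-F404D
1.7347,3.769,PC9-F404D
1.8367,4.907,PC9-F404D
1.9388,5.145,PC9-F404D
2.0408,3.018,PC9-F404D
2.1429,3.498,PC9-F404D
2.2449,1.531,PC9-F404D
2.3469,3.824,PC9-F404D
2.449,4.993,PC9-F404D
2.551,3.173,PC9-F404D
2.6531,2.411,PC9-F404D
2.7551,0.318,PC9-F404D
2.8571,2.015,PC9-F404D
2.9592,0.186,PC9-F404D
3.0612,3.045,PC9-F404D
3.1633,4.046,PC9-F404D
3.2653,3.621,PC9-F404D
3.3673,2.34,PC9-F404D
3.4694,2.658,PC9-F404D
3.5714,1.442,PC9-F404D
3.6735,2.361,PC9-F404D
3.7755,2.351,PC9-F404D
3.8776,2.091,PC9-F404D
3.9796,-0.655,PC9-F404D
4.0816,2.353,PC9-F404D
4.1837,2.538,PC9-F404D
4.2857,1.284,PC9-F404D
4.3878,2.496,PC9-F404D
4.4898,2.88,PC9-F404D
4.5918,-0.183,PC9-F404D
4.6939,2.961,PC9-F404D
4.7959,1.485,PC9-F404D
4.898,0.801,PC9-F404D
5.0,2.135,PC9-F404D
0.0,101.103,C9-35-12
0.102,64.83,C9-35-12
0.2041,44.587,C9-35-12
0.3061,28.236,C9-35-12
0.4082,21.02,C9-35-12
0.5102,12.185,C9-35-12
0.6122,8.97,C9-35-12
0.7143,6.418,C9-35-12
0.8163,3.182,C9-35-12
0.9184,5.003,C9-35-12
1.0204,1.855,C9-35-12
1.1224,1.613,C9-35-12
1.2245,2.037,C9-35-12
1.3265,3.138,C9-35-12
1.4286,1.444,C9-35-12
1.5306,4.157,C9-35-12
1.6327,2.085,C9-35-12
1.7347,1.783,C9-35-12
1.8367,2.496,C9-35-12
1.9388,1.9,C9-35-12
2.0408,0.962,C9-35-12
2.1429,1.463,C9-35-12
2.2449,2.175,C9-35-12
2.3469,3.583,C9-35-12
2.449,2.267,C9-35-12
2.551,2.478,C9-35-12
2.6531,-0.236,C9-35-12
2.7551,1.733,C9-35-12
2.8571,1.973,C9-35-12
2.9592,3.76,C9-35-12
3.0612,3.594,C9-35-12
3.1633,2.119,C9-35-12
3.2653,2.528,C9-35-12
3.3673,1.931,C9-35-12
3.4694,1.269,C9-35-12
3.5714,2.016,C9-35-12
3.6735,1.623,C9-35-12
3.7755,2.323,C9-35-12
3.8776,2.682,C9-35-12
3.9796,1.799,C9-35-12
4.0816,3.114,C9-35-12
4.1837,0.869,C9-35-12
4.2857,2.013,C9-35-12
4.3878,2.201,C9-35-12
4.4898,0.162,C9-35-12
4.5918,2.623,C9-35-12
4.6939,2.718,C9-35-12
4.7959,3.722,C9-35-12
4.898,1.955,C9-35-12
5.0,2.61,C9-35-12
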