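ID,Operation,Level,Time-CHKP-1 (ms),Time-CHKP-2 (ms),Total Time (ms),Errors,Performance Ratio (ms/E)
1,Bin,2,29288.28,54748.03,79828.34,80,997.84
2,Bin,2,24905.60,52536.68,94997.36,34,2794.04
3,Bin,2,32797.24,57092.38,78803.16,43,1832.62
4,Bin,2,27144.63,54854.24,78771.96,45,1750.49
5,Bin,2,25418.80,122261.47,147652.17,35,4218.62
5,Mon-Izq,2,25599.37,53875.00,82635.54,43,1921.76
6,Bin,2,89477.95,141704.12,176117.06,26,6773.72
7,Bin,2,30138.57,55496.31,81729.00,34,2403.78
8,Bin,2,27028.62,51896.15,76994.55,64,1203.04
9,Bin,2,29031.57,59622.15,89168.22,5,17833.63
10,Bin,2,32637.31,55022.04,78409.00,56,1400.16
11,Bin,2,30819.88,59929.77,87561.94,33,2653.38
12,Bin,2,29025.76,58571.12,86799.60,4,21699.89
13,Bin,2,29824.20,70036.41,96069.72,55,1746.71
14,Bin,2,32495.59,64573.82,91083.19,11,8280.29
15,Bin,2,28782.37,65735.45,93404.82,2,46702.41
15,Mon-Der,2,26546.87,50923.96,75681.78,36,2102.26
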