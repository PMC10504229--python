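accession,Asp,Thr,Ser,Glu,Gly,Ala,Cys,Val,Met,Ile,Leu,Tyr,Phe,Lys,His,Arg,Pro
IRIS_313.8412,1.56,0.56,0.77,3.02,0.66,0.95,0.28,0.80,0.08,0.43,1.29,0.35,0.86,0.62,0.39,1.27,0.23
CX237,1.54,0.53,0.73,2.81,0.66,0.96,0.24,0.83,0.04,0.54,1.26,0.43,0.82,0.64,0.38,1.34,0.29
IRIS_313.9560,1.38,0.51,0.69,2.63,0.57,0.83,0.24,0.72,0.09,0.49,1.15,0.44,0.74,0.53,0.31,1.12,0.20
IRIS_313.11796,1.31,0.47,0.64,2.47,0.59,0.88,0.24,0.69,0.13,0.44,1.08,0.39,0.73,0.60,0.36,1.14,0.33
IRIS_313.7778,1.34,0.49,0.66,2.49,0.57,0.84,0.22,0.68,0.00,0.47,1.10,0.43,0.76,0.61,0.34,1.07,0.42
IRIS_313.7832,1.36,0.50,0.67,2.56,0.57,0.83,0.22,0.68,0.00,0.46,1.11,0.36,0.72,0.55,0.33,1.13,0.43
B051,1.40,0.52,0.67,2.46,0.59,0.79,0.25,0.69,0.06,0.46,1.07,0.40,0.73,0.60,0.35,1.16,0.21
IRIS_313.11731,1.25,0.47,0.63,2.49,0.57,0.88,0.23,0.73,0.06,0.47,1.09,0.33,0.74,0.58,0.32,1.08,0.40
IRIS_313.10067,1.46,0.54,0.67,1.74,0.62,0.88,0.25,0.76,0.09,0.48,1.10,0.36,0.74,0.64,0.36,1.24,0.35
IRIS_313.11297,1.25,0.46,0.63,2.40,0.56,0.81,0.26,0.73,0.11,0.47,1.06,0.35,0.67,0.56,0.33,1.10,0.33
IRIS_313.10333,1.40,0.50,0.65,2.38,0.56,0.78,0.22,0.65,0.04,0.43,1.04,0.38,0.69,0.55,0.33,1.05,0.40
IRIS_313.11802,1.22,0.45,0.62,2.43,0.54,0.85,0.22,0.72,0.08,0.48,1.09,0.34,0.73,0.55,0.31,1.05,0.37
CX225,1.34,0.50,0.63,2.50,0.56,0.82,0.22,0.70,0.04,0.44,1.05,0.32,0.69,0.53,0.31,1.06,0.29
IRIS_313.11307,1.19,0.47,0.60,2.29,0.54,0.78,0.27,0.66,0.13,0.43,0.97,0.34,0.66,0.57,0.32,1.02,0.26
IRIS_313.11120,1.15,0.44,0.58,2.13,0.53,0.77,0.23,0.64,0.10,0.41,0.95,0.47,0.60,0.57,0.32,0.99,0.41
IRIS_313.11261,1.14,0.44,0.59,2.34,0.51,0.76,0.26,0.68,0.10,0.42,0.98,0.30,0.66,0.50,0.30,0.98,0.29
IRIS_313.10967,1.26,0.47,0.67,1.53,0.58,0.82,0.23,0.69,0.09,0.43,1.01,0.24,0.64,0.60,0.35,1.15,0.28
IRIS_313.10224,1.26,0.47,0.67,1.63,0.53,0.80,0.24,0.66,0.04,0.45,1.04,0.34,0.68,0.51,0.30,1.00,0.41
IRIS_313.9922,1.31,0.51,0.67,1.62,0.55,0.76,0.23,0.64,0.14,0.41,0.98,0.26,0.67,0.52,0.32,1.03,0.39
IRIS_313.8571,1.26,0.48,0.67,1.58,0.52,0.75,0.22,0.65,0.14,0.41,0.97,0.25,0.66,0.50,0.30,1.00,0.39
B043,1.19,0.43,0.59,2.10,0.50,0.66,0.20,0.57,0.04,0.39,0.94,0.38,0.75,0.58,0.31,0.97,0.13
IRIS_313.9503,1.26,0.46,0.88,1.46,0.53,0.75,0.20,0.62,0.02,0.40,0.94,0.32,0.65,0.56,0.30,1.01,0.37
IRIS_313.11599,1.14,0.44,0.87,1.43,0.54,0.78,0.20,0.66,0.06,0.40,0.91,0.36,0.62,0.59,0.31,1.01,0.22
IRIS_313.10430,1.17,0.40,0.89,1.38,0.54,0.74,0.19,0.60,0.00,0.40,0.96,0.45,0.66,0.52,0.30,1.09,0.23
IRIS_313.11854,1.06,0.42,0.54,2.01,0.49,0.71,0.23,0.62,0.05,0.40,0.87,0.47,0.61,0.52,0.28,0.92,0.22
IRIS_313.10151,1.16,0.41,0.86,1.42,0.51,0.72,0.19,0.61,0.04,0.38,0.92,0.28,0.61,0.49,0.29,1.00,0.24
IRIS_313.8641,1.12,0.43,0.84,1.42,0.48,0.70,0.21,0.58,0.06,0.38,0.90,0.28,0.59,0.46,0.27,0.92,0.28
IRIS_313.11824,0.98,0.37,0.48,1.84,0.47,0.69,0.22,0.59,0.15,0.36,0.83,0.30,0.57,0.49,0.26,0.85,0.29
IRIS_313.9771,1.08,0.39,0.51,1.82,0.43,0.57,0.18,0.51,0.03,0.34,0.79,0.34,0.66,0.64,0.26,0.83,0.27
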