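locus,LG,Ho,He,N,PIC
BoSF2304b,C09,0.0,0.48,5,0.43
BoESSR303,C04,0.0,0.33,4,0.31
BoSF1740,C08,0.0,0.63,5,0.57
BoESSR333,C04,0.0,0.81,9,0.77
BoSF378,C08,0.0,0.72,4,0.65
BoESSR338,C08,0.0,0.77,8,0.72
BoSF2680,C08,0.0,0.78,5,0.73
BoESSR403,C08,0.0,0.72,7,0.66
BoSF2054,C06,0.0,0.52,3,0.41
BoESSR409,C04,0.0,0.78,6,0.73
BoSF1215,C06,0.0,0.59,6,0.54
BoESSR576,C06,0.0,0.71,6,0.65
BoSF250,C06,0.0,0.67,3,0.58
BoESSR581,C06,0.0,0.67,7,0.62
BoSF2505,C06,0.0,0.6,4,0.54
BoESSR632,C01,0.0,0.71,6,0.67
BoSF2374,C05,0.0,0.62,4,0.54
BoESSR901,C09,0.0,0.77,7,0.73
BoSF1846,C05,0.0,0.69,4,0.62
BoESSR766,C03,0.0,0.69,7,0.63
BoSF2878,C05,0.0,0.57,3,0.48
BoESSR825,,0.0,0.69,7,0.63
BoSF912,C01,0.0,0.72,6,0.67
BoESSR673,C03,0.0,0.66,5,0.58
BoSF063,C01,0.0,0.74,8,0.69
BoESSR758,C07,0.0,0.68,7,0.64
BoSF2294a,C02,0.19,0.73,6,0.67
BoESSR763,C04,0.0,0.8,8,0.76
BoSF2615,C02,0.0,0.61,4,0.55
BoESSR863,C06,0.0,0.69,4,0.62
BoSF1167,C02,0.0,0.79,6,0.75
BoESSR903,C06,0.0,0.5,5,0.46
BoSF2248,C03,0.0,0.6,5,0.55
Na12F03a,C07,0.07,0.83,8,0.8
BoSF2232,C03,0.03,0.49,3,0.38
O110B11,C05,0.0,0.65,4,0.57
BoSF184,C04,0.0,0.73,7,0.68
BoSF2406,C07,0.03,0.67,7,0.62
BoSF1640,C09,0.0,0.43,2,0.33
BoSF2313,C07,0.07,0.75,8,0.7
BoSF2612,C08,0.0,0.67,4,0.59
BoSF2033,C07,0.0,0.81,9,0.77
BoSF2860,C07,0.04,0.76,8,0.71
BoSF317,C05,0.0,0.7,6,0.66
BoSF2345,C01,0.0,0.76,5,0.71
BoSF2421,C09,0.03,0.61,6,0.57
BoSF1207,C01,0.07,0.77,8,0.73
BoSF1957,C04,0.0,0.82,8,0.77
BoSF042,C03,0.0,0.73,6,0.68
Na12B09,C03,0.0,0.7,6,0.66
BoSF062,C03,0.03,0.51,5,0.46
cnu107,C02,0.0,0.27,3,0.24
BoSF2985,C03,0.0,0.68,4,0.6
BoSF1131,C03,0.0,0.78,7,0.73
BoE862,C04,0.0,0.75,6,0.7
BoSF966,C03,0.0,0.8,7,0.75
BRAS011,C02,0.03,0.77,10,0.73
CB10258,C01,0.0,0.78,8,0.73
BrBAC214,C03,0.0,0.48,5,0.43
BoESSR920,C09,0.0,0.79,6,0.73
BoESSR080,C07,0.03,0.78,9,0.73
BoESSR041,C06,0.0,0.83,8,0.79
BoESSR086,C03,0.0,0.63,6,0.58
BoESSR934,C08,0.0,0.65,4,0.57
BoESSR087,C04,0.0,0.7,5,0.65
Ni4D12,C02,0.0,0.57,3,0.48
BoESSR089,C01,0.0,0.8,7,0.76
cnu149,C05,0.0,0.81,8,0.76
BoESSR105,C04,0.0,0.76,6,0.71
BoESSR482,C02,0.0,0.79,7,0.75
BoESSR108,C04,0.0,0.67,5,0.6
O112G04a,C08,0.0,0.44,4,0.4
BoESSR122,C02,0.0,0.82,8,0.78
BoESSR492,C03,0.0,0.76,8,0.72
BoESSR151,C02,0.0,0.7,6,0.65
BoESSR510,C03,0.0,0.59,4,0.51
BoESSR206,C05,0.0,0.53,4,0.47
BoESSR523,C07,0.0,0.76,7,0.71
BoESSR207,C05,0.0,0.78,5,0.72
BoESSR560,C03,0.0,0.73,6,0.67
BoESSR208,C04,0.0,0.71,8,0.66
BoESSR736,C05,0.0,0.66,5,0.61
BoESSR212,C07,0.0,0.56,4,0.51
BoESSR030,C03,0.0,0.76,8,0.71
BoESSR216,C01,0.0,0.76,5,0.7
BoESSR073,C03,0.0,0.5,6,0.46
BoESSR248,C04,0.0,0.62,5,0.57
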