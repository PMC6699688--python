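source,df,CI,CM,PH,GPW,MCW,NCW,LL,LW,NoL,CL,CD,CoL,CSI,LSI,HI,TMY
Replicates,2,0.25,0.83,8.75,23153.58,11384.77,2565.82,1.65,6.04,2.92,1.28,1.07,0.01,181.72,3407.57,6.81,18.22
Treatments,145,6.08,299.66,176.18,1095365.25,266871.75,106378.93,175.89,43.16,29.54,2.35,5.11,1.23,1325.33,348863.53,238.79,426.99
Parents,25,13.28,563.97,113.34,403231.69,157665.16,56107.28,106.85,29.26,38.75,1.07,3.7,0.95,736.22,169525.92,305.09,252.26
Parents (Line),19,15.26,598.47,116.59,324516.0,129477.23,47982.0,104.48,34.83,40.96,1.21,4.14,1.08,820.98,190813.19,323.77,207.16
Parents (Testers),5,7.26,35.52,32.52,93011.02,92945.55,59482.5,72.38,13.26,15.33,0.78,2.77,0.61,561.34,88306.48,292.54,148.71
Parents (L vs T),1,5.75,2550.53,455.84,3449932.75,1016833.69,193611.64,324.21,3.48,113.78,0.0,0.0,0.01,0.17,171165.05,12.92,1626.93
Parents vs Crosses,1,29.58,1020.72,5878.71,31342492.0,4855010.5,1962991.75,2546.75,330.86,0.79,61.33,168.99,16.64,43832.41,3937259.75,1887.12,7768.02
Crosses,119,4.37,238.08,141.46,986594.0,251258.53,101338.41,170.48,43.66,27.84,2.12,4.03,1.16,1091.89,356384.91,211.01,402.01
Line Effect,19,5.53,1054.16,222.35,1737689.88,335689.69,114123.88,270.94,86.83,33.27,2.2,3.84,1.39,1097.96,670563.13,226.6,537.1
Tester Effect,5,5.06,33.96,65.61,694204.25,153128.39,47422.77,180.44,49.83,23.3,0.1,3.1,0.58,264.71,413817.59,132.45,245.01
Line x Tester Eff.,95,4.1,85.61,129.27,851763.75,239537.05,101618.98,149.86,34.71,27.0,2.21,4.11,1.15,1134.21,290526.47,212.03,383.26
Error,290,1.2,4.94,11.04,20306.63,10387.84,3296.66,4.67,1.96,4.07,0.64,0.61,0.11,157.99,8677.53,27.14,16.62
Total,437,2.82,102.71,65.82,377032.5,95495.77,37496.81,61.47,15.65,12.51,1.21,2.11,0.48,545.43,121529.77,97.27,152.79
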