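component,CI,CM,PH,GPW,MCW,NCW,LL,LW,NoL,CL,CD,CoL,CSI,LSI,HI,TMY
s2_gca_line,0.24,58.29,11.74,95410.18,18072.32,6157.07,14.79,4.71,1.62,0.09,0.18,0.07,52.22,36771.42,11.08,28.92
s2_gca_tester,0.06,0.48,0.91,11231.63,2379.01,735.44,2.93,0.8,0.32,-0.01,0.04,0.01,1.78,6752.33,1.76,3.81
s2_gca_avg,0.1,13.82,3.41,30657.45,6000.54,1986.58,5.67,1.7,0.62,0.01,0.07,0.02,13.42,13679.82,3.91,9.6
s2_sca,0.97,26.89,39.41,277152.38,76383.07,32774.11,48.4,10.92,7.64,0.52,1.17,0.34,325.41,93949.65,61.63,122.21
s2_A,0.21,27.65,6.82,61314.89,12001.09,3973.16,11.33,3.4,1.24,0.03,0.15,0.04,26.84,27359.63,7.81,19.2
s2_D,0.97,26.89,39.41,277152.38,76383.07,32774.11,48.4,10.92,7.64,0.52,1.17,0.34,325.41,93949.65,61.63,122.21
ratio_AD,0.22,1.03,0.17,0.22,0.16,0.12,0.23,0.31,0.16,0.05,0.13,0.13,0.08,0.29,0.13,0.16
degree_of_dominance,2.15,0.99,2.4,2.13,2.52,2.87,2.07,1.79,2.48,4.46,2.82,2.78,3.48,1.85,2.81,2.52
h2_narrow_pct,13.31,49.21,13.66,17.76,13.07,10.5,18.49,22.73,12.13,3.44,9.67,10.48,6.63,22.03,9.96,13.07
genetic_advance,0.34,7.6,1.99,214.97,81.57,42.07,2.98,1.81,0.8,0.06,0.25,0.14,2.75,159.92,1.82,3.26
predictability_ratio,0.18,0.51,0.15,0.18,0.14,0.11,0.19,0.24,0.14,0.05,0.11,0.11,0.08,0.23,0.11,0.14
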