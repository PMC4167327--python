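state,mean,sd,cv,min,q1,median,q3,max,citation,flag
AL,9.30,4.05,43.55,4.10,5.65,8.45,11.85,17.80,"Table 1, AL row",
FL,8.94,3.51,39.26,4.00,5.50,8.75,12.05,14.90,"Table 1, FL row",
GA,7.46,3.17,42.49,3.60,4.70,6.80,9.25,15.40,"Table 1, GA row",
IL,8.74,2.82,32.27,4.60,6.25,8.50,11.10,14.40,"Table 1, IL row",
LA,8.06,2.61,32.38,3.90,5.80,8.10,9.60,13.70,"Table 1, LA row",
MD,6.80,3.11,45.74,2.90,4.15,6.30,8.10,14.80,"Table 1, MD row",
MS,8.72,2.21,25.34,4.70,7.20,8.60,10.30,13.40,"Table 1, MS row",
NY,7.33,3.04,41.47,3.20,5.05,6.40,8.85,14.90,"Table 1, NY row",
NC,8.45,4.30,0.89,3.40,4.25,8.15,10.45,19.50,"Table 1, NC row","printed CV 0.89 is inconsistent with 100*4.30/8.45 = 50.89"
PA,6.78,2.33,34.37,2.70,5.35,6.80,8.15,11.80,"Table 1, PA row","state narrative reports Black median 8.15 vs 6.80 printed here"
SC,8.54,3.23,37.82,4.10,5.65,8.00,10.90,15.70,"Table 1, SC row",
TN,9.02,3.20,35.48,3.20,6.20,8.85,11.25,17.30,"Table 1, TN row",
TX,7.67,2.48,32.33,3.70,5.70,7.70,9.15,13.80,"Table 1, TX row",
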