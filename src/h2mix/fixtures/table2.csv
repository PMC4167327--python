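state,mean,sd,cv,min,q1,median,q3,max,citation,flag
AL,3.45,1.14,33.04,2.00,2.55,3.00,4.55,6.00,"Table 2, AL row",
FL,3.02,0.72,23.84,2.10,2.35,3.00,3.40,5.50,"Table 2, FL row","state narrative reports White mean 3.43 vs 3.02 printed here"
GA,3.43,0.74,21.57,2.40,2.90,3.30,3.70,4.60,"Table 2, GA row",
IL,3.09,0.71,22.98,2.10,2.50,3.00,3.60,5.20,"Table 2, IL row",
LA,2.86,0.72,25.17,1.60,2.50,2.75,3.25,6.20,"Table 2, LA row",
MD,2.82,1.13,40.07,1.40,2.05,2.40,3.25,5.20,"Table 2, MD row",
MS,2.90,0.74,25.52,1.70,2.45,2.80,3.20,4.40,"Table 2, MS row",
NY,3.00,0.69,23,1.80,2.35,3.05,3.45,4.90,"Table 2, NY row",
NC,2.91,0.85,29.21,1.60,2.25,2.75,3.60,4.70,"Table 2, NC row",
PA,2.92,0.70,23.97,1.80,2.40,2.95,3.30,5.10,"Table 2, PA row",
SC,3.12,1.00,32.05,1.30,2.40,2.95,4.00,6.00,"Table 2, SC row",
TN,3.57,1.04,29.13,1.90,2.90,3.30,4.15,5.10,"Table 2, TN row",
TX,3.45,0.61,17.68,2.50,3.00,3.50,3.65,5.50,"Table 2, TX row",
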