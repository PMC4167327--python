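row,estimate,se,df,t_value,p_value,alpha,lower,upper,gradient,citation,flag
1,13.1361,0.3877,24,33.89,<.0001,0.05,12.3360,13.9361,0.000811,"Table 5, row 1","row labels are unreadable in the source; no parameter-name mapping is claimed"
2,553.72,103.74,24,5.34,<.0001,0.05,339.62,767.82,0.005632,"Table 5, row 2","row labels are unreadable in the source; no parameter-name mapping is claimed"
3,12.6426,0.4053,24,31.20,<.0001,0.05,11.8062,13.4790,0.001518,"Table 5, row 3","row labels are unreadable in the source; no parameter-name mapping is claimed"
4,-0.2230,0.01105,24,-20.18,<.0001,0.05,-0.2457,-0.2002,0.019119,"Table 5, row 4","row labels are unreadable in the source; no parameter-name mapping is claimed"
5,-0.5316,0.1402,24,-3.79,0.0009,0.05,-0.8210,-0.2421,-0.00066,"Table 5, row 5","row labels are unreadable in the source; no parameter-name mapping is claimed"
6,-8.7847,0.5171,24,-16.99,<.0001,0.05,-9.8520,-7.7173,0.000311,"Table 5, row 6","row labels are unreadable in the source; no parameter-name mapping is claimed"
7,1.5196,0.4481,24,3.39,0.0024,0.05,0.5947,2.4445,-0.00011,"Table 5, row 7","row labels are unreadable in the source; no parameter-name mapping is claimed"
8,18816,1.6293,24,11548.6,<.0001,0.05,18813,18820,-0.00014,"Table 5, row 8","row labels are unreadable in the source; no parameter-name mapping is claimed"
9,96.7737,31.6337,24,3.06,0.0054,0.05,31.4849,162.06,-0.00004,"Table 5, row 9","row labels are unreadable in the source; no parameter-name mapping is claimed"
10,1.0442,0.04962,24,21.05,<.0001,0.05,0.9418,1.1467,-0.00014,"Table 5, row 10","row labels are unreadable in the source; no parameter-name mapping is claimed"
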