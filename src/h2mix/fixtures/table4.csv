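year,mean,sd,cv,min,q1,median,q3,max,citation,flag
1975,4.88,0.75,15.37,3.90,4.40,4.70,5.10,6.20,"Table 4, 1975 row",
1976,4.78,0.58,12.14,3.90,4.40,4.70,5.20,5.60,"Table 4, 1976 row",
1977,4.37,0.73,16.71,3.10,4.10,4.30,4.60,5.90,"Table 4, 1977 row",
1978,4.35,0.54,12.42,3.60,4.10,4.30,4.30,5.30,"Table 4, 1978 row",
1979,3.97,0.69,17.39,3.00,3.60,3.90,4.20,5.30,"Table 4, 1979 row",
1980,3.88,0.74,19.08,2.40,3.50,3.80,4.20,5.00,"Table 4, 1980 row",
1981,3.79,0.40,10.56,3.20,3.50,3.80,4.00,4.50,"Table 4, 1981 row",
1982,3.58,0.72,20.12,2.30,3.40,3.50,3.90,4.70,"Table 4, 1982 row",
1983,3.52,0.52,14.78,2.90,3.10,3.40,4.00,4.60,"Table 4, 1983 row",
1984,3.65,0.78,21.37,2.10,3.30,3.60,3.70,5.40,"Table 4, 1984 row",
1985,3.41,0.47,13.79,2.40,3.30,3.40,3.60,4.20,"Table 4, 1985 row",
1986,3.19,0.58,18.19,2.00,3.10,3.20,3.50,4.00,"Table 4, 1986 row",
1987,3.36,0.64,19.05,2.40,3.10,3.30,3.60,4.90,"Table 4, 1987 row",
1988,3.08,0.52,16.89,2.20,2.80,3.10,3.30,4.20,"Table 4, 1988 row",
1989,3.11,0.47,15.12,2.60,2.90,3.00,3.10,4.50,"Table 4, 1989 row",
1990,3.08,0.45,14.62,2.30,2.70,3.10,3.50,3.70,"Table 4, 1990 row",
1991,2.96,0.34,11.49,2.20,2.90,3.00,3.10,3.50,"Table 4, 1991 row",
1992,3.06,0.42,13.73,2.40,2.80,3.00,3.30,3.80,"Table 4, 1992 row",
1993,3.03,0.41,13.54,2.40,2.80,3.00,3.30,3.70,"Table 4, 1993 row",
1994,3.15,0.45,14.29,2.70,2.90,3.00,3.30,4.20,"Table 4, 1994 row",
1995,2.83,0.41,14.49,2.10,2.60,2.80,3.10,3.50,"Table 4, 1995 row",
1996,2.85,0.33,11.58,2.40,2.70,2.90,3.10,3.50,"Table 4, 1996 row",
1997,2.97,0.45,15.16,2.50,2.70,2.80,3.20,4.10,"Table 4, 1997 row",
1998,2.78,0.48,17.27,1.90,2.60,2.90,3.10,3.70,"Table 4, 1998 row",
1999,2.72,0.33,12.14,2.00,2.60,2.70,2.90,3.30,"Table 4, 1999 row",
2000,2.54,0.54,21.26,1.30,2.40,2.50,2.90,3.50,"Table 4, 2000 row",
2001,2.49,0.40,16.07,1.80,2.30,2.40,2.70,3.10,"Table 4, 2001 row",
2002,2.45,0.45,18.37,1.70,2.20,2.30,2.70,3.40,"Table 4, 2002 row",
2003,2.25,0.56,24.89,1.40,1.90,2.20,2.40,3.50,"Table 4, 2003 row",
2004,2.26,0.54,23.9,1.40,1.90,2.20,2.40,3.30,"Table 4, 2004 row",
2005,2.35,0.41,17.45,1.50,2.20,2.40,2.70,2.90,"Table 4, 2005 row",
2006,2.31,0.41,17.75,1.80,2.00,2.30,2.50,3.10,"Table 4, 2006 row",
2007,2.35,0.36,15.32,1.70,2.10,2.40,2.50,2.90,"Table 4, 2007 row",
2008,2.38,0.39,16.39,1.80,2.10,2.40,2.70,3.00,"Table 4, 2008 row",
2009,2.25,0.51,22.67,1.70,2.10,2.10,2.40,3.70,"Table 4, 2009 row",
2010,2.24,0.40,17.86,1.60,2.00,2.30,2.50,2.90,"Table 4, 2010 row",
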