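year,mean,sd,cv,min,q1,median,q3,max,citation,flag
1975,13.95,2.61,18.71,9.70,12.40,13.80,14.90,17.70,"Table 3, 1975 row",
1976,12.95,2.73,21.09,9.40,11.20,12.10,14.70,19.50,"Table 3, 1976 row",
1977,12.88,2.22,17.24,9.60,11.60,13.00,14.40,17.80,"Table 3, 1977 row",
1978,12.90,2.35,18.22,8.50,11.80,12.40,14.60,17.70,"Table 3, 1978 row",
1979,10.75,2.44,22.7,6.90,9.00,10.20,13.00,14.40,"Table 3, 1979 row",
1980,11.46,2.10,18.33,8.70,9.50,11.70,13.00,14.40,"Table 3, 1980 row",
1981,10.38,2.07,19.95,7.70,8.90,10.00,11.60,14.40,"Table 3, 1981 row",
1982,10.46,2.06,19.7,7.20,8.30,10.70,11.80,13.50,"Table 3, 1982 row",
1983,10.56,1.92,18.19,7.40,8.40,11.30,11.50,13.40,"Table 3, 1983 row",
1984,10.44,1.69,16.19,7.70,9.40,10.30,11.60,13.00,"Table 3, 1984 row",
1985,9.75,1.72,17.65,7.10,8.20,9.70,11.30,12.00,"Table 3, 1985 row",
1986,10.18,1.90,18.67,7.10,8.80,10.10,11.10,13.80,"Table 3, 1986 row",
1987,8.72,1.61,18.47,6.20,7.80,8.80,9.50,11.80,"Table 3, 1987 row",
1988,8.52,2.14,25.12,5.00,7.50,8.00,9.90,11.80,"Table 3, 1988 row",
1989,9.15,2.17,23.72,6.10,7.90,8.60,10.30,13.20,"Table 3, 1989 row",
1990,8.31,1.53,18.42,5.00,7.50,8.50,8.70,10.90,"Table 3, 1990 row",
1991,8.19,1.44,17.59,6.30,7.60,7.90,8.70,11.40,"Table 3, 1991 row",
1992,8.93,1.99,22.29,5.70,7.10,9.10,10.30,12.00,"Table 3, 1992 row",
1993,8.54,1.21,14.17,7.00,7.50,8.30,9.30,10.70,"Table 3, 1993 row",
1994,7.38,1.10,14.91,5.50,6.80,7.60,8.10,8.80,"Table 3, 1994 row",
1995,7.74,1.52,19.64,5.50,6.60,7.90,8.40,11.20,"Table 3, 1995 row",
1996,6.75,1.33,19.71,5.00,5.70,6.20,8.00,8.90,"Table 3, 1996 row",
1997,7.05,0.93,13.2,6.00,6.40,6.90,7.80,8.70,"Table 3, 1997 row",
1998,6.23,0.98,15.74,4.90,5.50,6.20,6.90,8.00,"Table 3, 1998 row",
1999,5.80,1.16,20,3.80,5.30,6.00,6.40,8.20,"Table 3, 1999 row",
2000,6.00,1.61,26.84,3.30,5.20,5.80,7.60,8.40,"Table 3, 2000 row",
2001,5.18,1.40,27.03,3.20,4.10,4.70,5.70,8.00,"Table 3, 2001 row",
2002,5.51,0.99,17.97,3.90,4.70,5.60,6.10,7.40,"Table 3, 2002 row",
2003,5.15,1.32,25.64,3.50,3.90,5.20,5.70,8.20,"Table 3, 2003 row",
2004,5.25,1.06,20.2,3.80,4.40,5.50,5.70,7.60,"Table 3, 2004 row",
2005,4.95,1.02,20.61,3.10,4.60,4.80,5.60,6.90,"Table 3, 2005 row",
2006,4.85,1.34,27.63,3.40,4.30,4.50,5.20,8.60,"Table 3, 2006 row",
2007,4.68,1.26,26.93,2.70,4.00,4.50,5.00,8.00,"Table 3, 2007 row",
2008,4.72,1.22,25.85,3.20,3.70,4.70,5.60,7.00,"Table 3, 2008 row",
2009,4.55,0.75,16.49,3.60,4.10,4.40,4.70,6.40,"Table 3, 2009 row",
2010,4.20,0.99,23.58,2.90,3.60,3.90,4.90,6.20,"Table 3, 2010 row",
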