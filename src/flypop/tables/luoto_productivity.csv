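year,J,R
1995,21,19
1996,19,18
1997,12,12
1998,22,17
1999,22,19
2000,17.5,13
2001,19,13
2002,20,19
2003,30,24
2004,16,17
2005,20,15
2006,12.5,9
2007,3,2
2008,4,4
2009,8,10
2010,12.5,12
2011,14.5,11
2012,25.5,16
2013,6,8
2014,12,10
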