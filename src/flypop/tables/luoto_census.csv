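year,y
1995,20
1996,22
1997,13
1998,22
1999,20
2000,17
2001,14
2002,22
2003,29
2004,19
2005,20
2006,10
2007,4
2008,9
2009,11
2010,13
2011,14
2012,20
2013,8
2014,10
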