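year,J,R
2002,27,21
2003,25,20
2004,8,13
2005,23,18
2006,45,35
2007,27,23
2008,33.5,32
2009,27,26
2010,19,18
2011,17,20
2012,24,16
2013,11,11
2014,17,15
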