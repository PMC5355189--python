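year,y
2002,28
2003,29
2004,19
2005,24
2006,43
2007,29
2008,47
2009,34
2010,28
2011,29
2012,28
2013,23
2014,23
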