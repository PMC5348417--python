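study_id	platform_size	n_cases	n_controls
Iorio2007	235	69	15
Nam2008	314	20	8
Dahiya2008	462	34	1
Yang2008	515	10	10
Wyman2009	498	33	4
Resnick2009	365	28	15
Kim2010	739	54	49
Elgaaen2014a	1105	35	9
Elgaaen2014b	1105	19	9
Dong2014	2064	5	5
Li2014	739	100	50
Shapira2014	754	42	36
Wang2014	1757	48	15
Ibrahim2015	85	22	22
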