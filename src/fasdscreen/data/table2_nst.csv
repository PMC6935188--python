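label,measure,proportion,group_n,sd
LaFrance 2014,sensitivity,0.63,48,0.069
LaFrance 2014,specificity,1.00,32,0.017
Breiner 2013,sensitivity,0.94,17,0.056
Breiner 2013,specificity,0.96,43,0.030
Nash 2011 (typical controls),sensitivity,0.98,56,0.019
Nash 2011 (typical controls),specificity,0.42,53,0.067
Nash 2011 (ADHD controls),sensitivity,0.89,56,0.041
Nash 2011 (ADHD controls),specificity,0.42,50,0.069
Nash 2006 (typical controls),sensitivity,0.86,30,0.062
Nash 2006 (typical controls),specificity,0.82,30,0.069
Nash 2006 (ADHD controls),sensitivity,0.81,30,0.070
Nash 2006 (ADHD controls),specificity,0.72,30,0.081
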