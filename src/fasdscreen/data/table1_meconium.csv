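label,measure,proportion,group_n,sd
Bakhireva 2014,sensitivity,1.00,28,0.019
Bakhireva 2014,specificity,0.13,32,0.059
Ostrea 2006,sensitivity,0.68,93,0.048
Ostrea 2006,specificity,0.29,31,0.080
Bearer 2003,sensitivity,1.00,21,0.021
Bearer 2003,specificity,0.67,6,0.178
Chan 2003,sensitivity,1.00,17,0.023
Chan 2003,specificity,0.98,183,0.010
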