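fl_lower_cm,fl_upper_cm,rate_cm_per_yr
50,110,40
110,180,21
180,265,18
265,400,6
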