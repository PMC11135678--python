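label,broad_type,subtype,adult,group2_calf,group5_calf,group6_calf
bop,LF tonal,bop,0.286,0,0.211,0.003
whup,LF pulsed,whup,0.127,0,0,0.009
grunt,LF tonal,grunt,0.116,0,0,0.015
knock,LF pulsed,knock,0.092,0.667,0,0.076
hf_tonal,HF tonal,,0.079,0,0.684,0.015
paired_burst,paired burst,,0.079,0,0,0
lf_pulsed_other,LF pulsed,other,0.056,0.333,0,0.218
complex,complex,,0.054,0,0,0.003
snort,LF pulsed,snort,0.022,0,0,0.170
lf_tonal_other,LF tonal,other,0.022,0,0.105,0.033
thwop,LF pulsed,thwop,0.016,0,0,0.109
other,other,,0.014,0,0,0.009
squish,LF pulsed,squish,0.013,0,0,0.109
pulse,pulse,,0.011,0,0,0.009
squelch,LF pulsed,squelch,0.010,0,0,0.139
pseudo-thwop,LF pulsed,pseudo-thwop,0.003,0,0,0.048
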