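standard,adduct,ccs_vendor,ccs_single_pass,pdiff_single_pass,ccs_multipass,pdiff_multipass
d7-PC (15:0-18:1),[M+H]+,292.8,289.1,1.28,288.6,1.44
d7-LysoPC (18:1),[M+H]+,236.0,238.9,1.22,238.8,1.19
d7-PE (15:0-18:1),[M+H]+,280.1,279.2,0.32,279.2,0.32
d7-LysoPE (18:1),[M+H]+,218.9,222.1,1.45,222.2,1.50
d7-LysoPE (18:1),[M+Na]+,225.1,228.2,1.38,228.2,1.37
d7-LysoPC (18:1),[M+Na]+,238.6,241.4,1.18,241.3,1.13
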