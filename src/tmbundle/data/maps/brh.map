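# bovine rhodopsin (1U19 and relatives); anchors pinned by Glu113=3.28, Arg135=3.50, Glu247=6.30, Lys296=7.43
helix1.50 = 55
helix2.50 = 83
helix3.50 = 135
helix4.50 = 161
helix5.50 = 215
helix6.50 = 267
helix7.50 = 303
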