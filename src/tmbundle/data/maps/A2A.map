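# human A2A adenosine receptor (3EML and relatives); standard conserved-residue anchors
helix1.50 = 24
helix2.50 = 52
helix3.50 = 102
helix4.50 = 129
helix5.50 = 189
helix6.50 = 248
helix7.50 = 285
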