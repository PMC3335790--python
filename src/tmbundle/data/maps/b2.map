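# human beta2 adrenergic receptor (2RH1 and relatives); standard conserved-residue anchors
helix1.50 = 51
helix2.50 = 79
helix3.50 = 131
helix4.50 = 158
helix5.50 = 211
helix6.50 = 288
helix7.50 = 323
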