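# human CXCR4 chemokine receptor (3ODU) — UNVERIFIED anchors: confirm against GPCRDB before production use
helix1.50 = 56
helix2.50 = 84
helix3.50 = 134
helix4.50 = 161
helix5.50 = 211
helix6.50 = 254
helix7.50 = 299
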