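# human M2 muscarinic receptor (3UON) — UNVERIFIED anchors: confirm against GPCRDB before production use
helix1.50 = 41
helix2.50 = 69
helix3.50 = 121
helix4.50 = 144
helix5.50 = 198
helix6.50 = 396
helix7.50 = 429
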