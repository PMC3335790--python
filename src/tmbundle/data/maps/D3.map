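# human dopamine D3 receptor (3PBL) — UNVERIFIED anchors: confirm against GPCRDB before production use
helix1.50 = 48
helix2.50 = 80
helix3.50 = 128
helix4.50 = 151
helix5.50 = 205
helix6.50 = 342
helix7.50 = 374
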