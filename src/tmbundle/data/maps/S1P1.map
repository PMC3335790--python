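# human S1P1 receptor (3V2Y) — UNVERIFIED anchors: confirm against GPCRDB before production use
helix1.50 = 59
helix2.50 = 87
helix3.50 = 142
helix4.50 = 165
helix5.50 = 218
helix6.50 = 268
helix7.50 = 301
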