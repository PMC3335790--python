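# human histamine H1 receptor (3RZE) — UNVERIFIED anchors: confirm against GPCRDB before production use
helix1.50 = 44
helix2.50 = 73
helix3.50 = 125
helix4.50 = 148
helix5.50 = 202
helix6.50 = 435
helix7.50 = 468
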