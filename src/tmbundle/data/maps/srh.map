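# squid rhodopsin (2Z73) — UNVERIFIED anchors: confirm against GPCRDB before production use
helix1.50 = 52
helix2.50 = 80
helix3.50 = 132
helix4.50 = 158
helix5.50 = 212
helix6.50 = 264
helix7.50 = 300
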