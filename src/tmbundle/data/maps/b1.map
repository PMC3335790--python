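# turkey beta1 adrenergic receptor (2VT4) — UNVERIFIED anchors: confirm against GPCRDB before production use
helix1.50 = 59
helix2.50 = 87
helix3.50 = 139
helix4.50 = 166
helix5.50 = 219
helix6.50 = 305
helix7.50 = 338
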