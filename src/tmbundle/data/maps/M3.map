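# rat M3 muscarinic receptor (4DAJ) — UNVERIFIED anchors: confirm against GPCRDB before production use
helix1.50 = 84
helix2.50 = 112
helix3.50 = 164
helix4.50 = 187
helix5.50 = 242
helix6.50 = 503
helix7.50 = 536
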