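# Terms that are valid LLT entries but almost always ordinary words in
# labeling prose; removed from the effective dictionary at load time.
all
high
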