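legacy	canonical
Firmicutes	Bacillota
Bacteroidetes	Bacteroidota
Actinobacteria	Actinomycetota
Tenericutes	Mycoplasmatota
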