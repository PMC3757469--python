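mutation_a,mutation_b
A141N,I189Y
A141Q,I189Y
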