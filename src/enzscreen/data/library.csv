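position,wt_residue,allowed_substitutions
39,G,A
103,T,G
104,W,"F,Q,Y"
141,A,"N,Q"
189,I,"A,G,H,N,Y"
278,L,A
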