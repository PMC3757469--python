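mutant,barrier_kcal_mol
G39A-T103G-I189Y,5.7
G39A-I189Y,6.2
G39A-A141Q-I189G-L278A,6.3
G39A-A141N-L278A,7.6
G39A-A141N,7.7
G39A-A141N-I189H-L278A,8.3
G39A-W104F-A141Q-I189A,8.3
G39A-A141Q-I189N,9.1
G39A-A141N-I189N,9.3
G39A-T103G-W104Y-A141N,9.8
G39A-W104Y-I189Y,9.8
G39A-A141N-I189N-L278A,10.1
G39A-W104F-A141N,10.1
G39A-I189H-L278A,10.2
G39A-A141N-I189A-L278A,10.2
W104Y-I189H,10.4
G39A-T103G-W104F-I189Y,10.4
G39A-A141Q-I189A-L278A,10.4
G39A-T103G-A141Q-I189H,10.4
G39A-T103G-I189A-L278A,10.5
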