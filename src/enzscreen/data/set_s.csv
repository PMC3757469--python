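mutant,activity_fold_wt,barrier_kcal_mol,organism
G39A-T103G-W104F-L278A,11.2,13.9,Ao
G39A-L278A,7.0,11.3,Pp
G39A-W104F,4.2,10.6,Ao
G39A-T103G-L278A,3.8,7.3,Ao
G39A-W104F-L278A,3.6,11.8,Pp
T103G,3.0,13.6,Ao
G39A-W104F-I189Y-L278A,2.9,10.9,Pp
G39A,2.8,11.2,Ao
L278A,2.5,12.8,Ao
W104F,2.0,12.0,Ao
G39A-T103G-W104Q-L278A,1.9,12.8,Ao
G39A-T103G-W104F-D223G-L278A,1.5,11.3,Pp
G39A-T103G,0.8,7.5,Ao
G39A-T42A-T103G-W104F-L278A,0.7,10.4,Pp
I189H,0.5,12.9,Pp
G39A-I189G-L278A,0.4,10.7,Pp
G41S,0.3,13.4,Pp
I189G,0.2,18.9,Pp
G39A-T103G-W104F-I189H-D223G-L278A,0.1,13.7,Pp
G39A-T103G-W104F-I189H-L278A-A282G-I285A-V286A,0.1,12.9,Pp
A132N,0.0,12.5,Pp
P38H,0.0,12.5,Pp
WT,1.0,7.5,
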