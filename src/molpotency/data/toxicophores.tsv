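name	smarts
Nitroso	N=O
Aliphatic halide	ClA,BrA,IA
Aromatic nitro	O=[N+]([O-])a
Aromatic amine	[NH2]a
Three-membered heterocycle	C1C[NH]1,C1CO1,C1CS1
Azo-type	N=N
Unsubstituted heteroatom-bonded heteroatom	N[NH2],N[OH],O[OH],O[NH2]
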