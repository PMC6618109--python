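species	required_names
Durusdinium trenchii	D1,D4
Cladocopium thermophilum	C3,C3gulf
Cladocopium goreaui	C1
Symbiodinium microadriaticum	A1
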