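component	side	pattern	modes
DFO	L	BABAA	standard,alt
DFO	L	BBBAA	standard
DFO	L	ABABA	standard,alt
DFO	L	AAABA	standard,alt
DFO	R	BAABA	standard,alt
DFO	R	BBABA	standard
DFO	R	ABBAA	standard,alt
DFO	R	AABAA	standard,alt
DIL	L	ABBAA	standard,alt
DIL	L	BBBAA	standard
DIL	L	BAABA	standard,alt
DIL	L	AAABA	standard,alt
DIL	R	ABABA	standard,alt
DIL	R	BBABA	standard
DIL	R	BABAA	standard,alt
DIL	R	AABAA	standard,alt
DFI	L	BABAA	standard,alt
DFI	L	BABBA	standard
DFI	L	ABABA	standard,alt
DFI	L	ABAAA	standard,alt
DFI	R	ABBAA	standard,alt
DFI	R	ABBBA	standard
DFI	R	BAABA	standard,alt
DFI	R	BAAAA	standard,alt
DOL	L	BAABA	standard,alt
DOL	L	BABBA	standard
DOL	L	ABBAA	standard,alt
DOL	L	ABAAA	standard,alt
DOL	R	ABABA	standard,alt
DOL	R	ABBBA	standard
DOL	R	BABAA	standard,alt
DOL	R	BAAAA	standard,alt
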