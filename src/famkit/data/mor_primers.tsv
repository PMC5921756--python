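name	sequence	amplicon_bp	distance_from_3prime_bp
MOR_5F	CGACCGTTGTCTGATTTTGTGA	81	1671
MOR_5R	GGCCATTTTCAGAACCCCTAA	81	1671
MOR_3F	GCTTCGAGCAGCAGTTGAAGAA	80	450
MOR_3R	CTTTTGACATGTGTGCAAGTT	80	450
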