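# Illustrative pathway definitions for `kefirmeta score-pathways`.
# These gene lists are simplified teaching examples, NOT curated pathway
# content; supply your own definitions for real analyses.
pathway	gene
L-lysine	lysC
L-lysine	asd
L-lysine	dapA
L-lysine	dapB
L-tryptophan	trpA
L-tryptophan	trpB
L-tryptophan	trpC
riboflavin	ribA
riboflavin	ribB
riboflavin	ribE
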