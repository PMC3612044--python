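id	sequence	length	n_hydrophobic	note
HI 1	HPHHPPHHHHPHHHPPHHPPHPHHHPHPHHPPHHPPPHPPPPPPPPHH	48	24	Harvard Instance
HI 2	HHHHPHHPHHHHHPPHPPHHPPHPPPPPPHPPHPPPHPPHHPPHHHPH	48	24	Harvard Instance
HI 3	PHPHHPHHHHHHPPHPHPPHPHHPHPHPPPHPPHHPPHHPPHPHPPHP	48	24	Harvard Instance
HI 4	PHPHHPPHPHHHPPHHPHHPPPHHHHHPPHHPHHPPHPPPPHPPHPHP	48	24	Harvard Instance
HI 5	PPHHPPHHPPHHHHPPHHHHPPHHPPHHPHPHPHPHPPPPPPHPHHPH	48	24	Harvard Instance (reconstructed: run-length glyphs ambiguous)
HI 6	HHPPHHPPHHPPHHPPHHPPHHPPHPPPPPPPHPHPHPHPHHHHHHPH	48	24	Harvard Instance (reconstructed: run-length glyphs ambiguous)
HI 7	PPHHPPPPHHPPHHPPHHPPHHHHPPHHPPHHPPHHPPHHPHPHPHPH	48	24	Harvard Instance (reconstructed: run-length glyphs ambiguous)
HI 8	PPHHPPHHPPHHHHPPHHPPPPPPHHPPHHPPHHPHHPHHPHHPHPHP	48	24	Harvard Instance (reconstructed: run-length glyphs ambiguous)
HI 9	PPHPHPPPPHPHPHPHPHHHHHHPHHPPHHPPHHPPHPHPHHHPPPPH	48	24	Harvard Instance (reconstructed: run-length glyphs ambiguous)
HI 10	PPHHPPPPPPHHPPHHPPHHPPHHPPHHPPHHPPHPPHPHHHHHHHPH	48	24	Harvard Instance (reconstructed: run-length glyphs ambiguous)
HI 9/2	PPHPHPPPPHPHPHPHPHHHHHHP	24	12	First half of HI 9 (reconstructed: run-length glyphs ambiguous)
F 90	PPHHPPHHPPPPHHPPHHHHHHPPHHPPHHPPHHPPHHHHHPPHHPHHPHHHHPHHPPPPHHPHHPHHPHHPHHPHHPHHPHPPPPHPHP	90	50	Seq. F 90_1 (reconstructed: run-length glyphs ambiguous)
S 1	HHHHPPHHHHHHPPHHPPHHHHHHHHPPHHPPHHHHHHHHHHPPHHPPPPPHHPPHHHHHHHHPPHHPPHHPPPHHHHHHHHPHHHHHHPHHHHHHHPHHPHHHHHHHHHPHPHHHHHHHPHPHHHHHHHPHHHH	135	100	Seq. S 1 (reconstructed: run-length glyphs ambiguous)
S 4	HHHHHHHHPPPPHHHHHHPPPPHHHPPPPHHHHHPPPPHHHHHHPPPPHHHHHHPPPPHHHHHHPPPPHHHHHHPPPPHHHHHHPPPPHHHHHHPPPPHHHHHHHPPPPHHHHHHPPPPHHHHHHPPPPHHHHHHPPPHHHHHHPPPHHHHHHPPPHHHHHPPP	164	100	Seq. S 4 (reconstructed: run-length glyphs ambiguous)
R 1	PPPPPPPPHHHHHHHHHPPPPPPPPPHHHHHHHHHPPPPPPPPPHHHHHHHHHPPPPPPPPPHHHHHHHHHPPPPPPPPHHHHHHHHHPPPPPPPPHHHHHHHHHPPPPPPPPHHHHHHHHPPPPPPPPHHHHHHHHPPPPHHHHHHPPPPPPPPHHHHHHHHPPPPPHHHHHHHHPPPPPPPPHHHHHHHHPPPPPPPP	200	100	Seq. R 1 (reconstructed: run-length glyphs ambiguous)
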