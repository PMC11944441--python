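enzyme	pattern	description
trypsin	(?<=[KR])(?!P)	cleaves after K or R, not before P
lys-c	(?<=K)	cleaves after K
arg-c	(?<=R)	cleaves after R
glu-c	(?<=E)	glutamyl endopeptidase; cleaves after E
chymotrypsin-high	(?<=[FYW])(?!P)	high-specificity chymotrypsin; after F/Y/W, not before P
pepsin-ph1.3	(?:(?<=[FL])(?!P))|(?=[FL])	simplified pepsin at pH 1.3; F or L at P1 (not before P) or P1'
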