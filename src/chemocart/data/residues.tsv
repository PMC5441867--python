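# monoisotopic residue masses (Da) for neutral-loss sequencing of (depsi)peptides
name	mass	note
Gly	57.02146	glycine
Ala	71.03711	alanine
N-Me-Gly	71.03711	sarcosine; isobaric with Ala
Ser	87.03203	serine
Pro	97.05276	proline
Val	99.06841	valine
Thr	101.04768	threonine
Hiv	100.05243	2-hydroxyisovaleric acid (hydroxy-acid residue of depsipeptides)
Leu/Ile	113.08406	leucine/isoleucine (isobaric, intentionally joint)
MeHiv	114.06808	methylated Hiv
Asp	115.02694	aspartate
Glu	129.04259	glutamate
Met	131.04049	methionine
Phe	147.06841	phenylalanine
Dhoya	166.09938	2,2-dimethyl-3-hydroxy-7-octynoic acid residue (C10H14O2)
Dhoea	168.11503	2,2-dimethyl-3-hydroxy-7-octenoic acid residue (C10H16O2)
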