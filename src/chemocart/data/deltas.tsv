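# exact mass deltas (Da) of common substituent changes between structural analogs
name	delta	note
methylation(+CH2)	14.01565	gain of CH2
demethylation(-CH2)	-14.01565	loss of CH2, e.g. N- or O-desmethyl analogs
saturation(+H2)	2.01565	alkene -> alkane (or alkyne -> alkene)
desaturation(-H2)	-2.01565	loss of H2
oxidation(+O)	15.99491	gain of oxygen
Leu->Phe(+C2H2O-free)	33.98435	Leu/Ile substituted by Phe
Phe->Leu	-33.98435	Phe substituted by Leu/Ile (conservative NRPS A-domain swap)
Cl-for-H	33.96102	chlorination (Cl replaces H)
H-for-Cl	-33.96102	dechlorination
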