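# Hydrocarbon screening panel: 39 hydrocarbons plus pentane solvent control.
# SYNTHETIC RECONSTRUCTION: panel membership and cuticle-presence flags were
# transcribed/reconstructed from figure label colouring and the cuticular-
# extract literature for Harpegnathos saltator, not from a machine-readable
# source; 17 of the 39 entries carry on_cuticle = 1 (odd-chain C25-C37 bias).
# methyl_positions: comma-joined integers, empty for none.
# double_bond: position with geometry prefix (e.g. Z9), empty for none.
name	chain_length	hc_class	methyl_positions	double_bond	on_cuticle
C10	10	n-alkane			0
C11	11	n-alkane			0
C12	12	n-alkane			0
C13	13	n-alkane			0
C14	14	n-alkane			0
C15	15	n-alkane			0
C16	16	n-alkane			0
C17	17	n-alkane			0
C18	18	n-alkane			0
C20	20	n-alkane			0
C21	21	n-alkane			0
C22	22	n-alkane			0
C23	23	n-alkane			0
C24	24	n-alkane			0
C25	25	n-alkane			1
C26	26	n-alkane			0
C27	27	n-alkane			1
C28	28	n-alkane			1
C29	29	n-alkane			1
C30	30	n-alkane			0
C31	31	n-alkane			1
C32	32	n-alkane			0
C33	33	n-alkane			1
C34	34	n-alkane			0
C35	35	n-alkane			1
11-MeC27	27	monomethyl	11		0
13-MeC27	27	monomethyl	13		1
2-MeC28	28	monomethyl	2		0
13-MeC29	29	monomethyl	13		1
15-MeC29	29	monomethyl	15		0
5-MeC31	31	monomethyl	5		1
13-MeC31	31	monomethyl	13		1
15-MeC31	31	monomethyl	15		1
13-MeC33	33	monomethyl	13		1
3,11-DiMeC29	29	dimethyl	3,11		0
13,23-DiMeC35	35	dimethyl	13,23		1
13,23-DiMeC37	37	dimethyl	13,23		1
Z9-C29:1	29	alkene		Z9	1
Z9-C31:1	31	alkene		Z9	1
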