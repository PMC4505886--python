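# Curated TCR structure set: 85 PDB entries (136 biological units).
# Columns: pdb_id, bu_chains (comma-separated alpha:beta pairs, one per BU),
# alpha_range, beta_range (inclusive author numbering of the V domains),
# bound_state (u/1/2/s), species (h/m), tcr_type, subtype.
# Chain assignments and V-domain ranges are deposition-specific and must be
# completed from each entry's biological-unit records and an IMGT V-domain
# delineation before running `vdomgeom align`; they are left blank here.
pdb_id	bu_chains	alpha_range	beta_range	bound_state	species	tcr_type	subtype
2bnu				u	h	1G4	wt
2bnq				1	h	1G4	wt
2bnr				1	h	1G4	wt
2f54				1	h	1G4	AV-wt
2pyf				u	h	1G4	c5c1
2pye				1	h	1G4	c5c1
2f53				1	h	1G4	c49c50
2p5w				1	h	1G4	c58c62
2p5e				1	h	1G4	c58c61
1zgl				2	h	3A6
2gj6				1	h	A6
1qsf				1	h	A6
1qse				1	h	A6
3d3v				1	h	A6
3d39				1	h	A6
1qrn				1	h	A6
1ao7				1	h	A6
3h9s				1	h	A6
3pwp				1	h	A6
3o4l				1	h	AS01
1bd2				1	h	B7
3ffc				1	h	cf34
3dxa				1	h	DM1
3dx9				u	h	DM1
2ian				2	h	E8
2iam				2	h	E8
2ial				u	h	E8
2nx5				1	h	ELS4
2nw2				u	h	ELS4
1fyt				2	h	HA1.7
1j8h				2	h	HA1.7
3pl6				1	h	Hy.1B1
2vlj				1	h	JM22
2vlk				1	h	JM22
1oga				1	h	JM22
2vlm				u	h	JM22
2xn9				s	h	JM22
2xna				s	h	JM22
2vlr				1	h	JM22	S99bA
2esv				1	h	KK50.4
1mi5				1	h	LC13
1kgc				u	h	LC13
3kpr				1	h	LC13
3kps				1	h	LC13
3hg1				1	h	MEL5
2wbj				2	h	OB.1A12
1ymm				2	h	OB.1A12
3gsn				1	h	RA14
2ak4				1	h	SB27
3kxf				1	h	SB27	K16Da
3o6f				2	h	MS2-3C8
3mv7				1	h	TK3	wt
3mv8				1	h	TK3	Q55H
3mv9				1	h	TK3	Q55A
2pxy				2	m	1934.4
3mff				u	m	1F1E8
3qiu				2	m	226
3qiw				2	m	226
3qib				1	m	2B4
3qjf				u	m	2B4
1tcr				u	m	2C	wt
1g6r				1	m	2C	wt
1mwa				1	m	2C	wt
2ckb				1	m	2C	wt
2icw				s	m	2C	T7
2oi9				1	m	2C	T7-wt-s
3e3q				1	m	2C	m13
2e7l				1	m	2C	m6
3e2h				1	m	2C	m67
3c6l				2	m	2W20
3qjh				u	m	5c.c7
2uwe				1	m	AHIII12.2
2jcc				1	m	AHIII12.2
1lp9				1	m	AHIII12.2
3c5z				2	m	B3K506
1nam				1	m	BM3.3
1fo0				1	m	BM3.3
2ol3				1	m	BM3.3
2z31				2	m	cl19
1d9k				2	m	D10
1kj2				1	m	KB5-C20
1nfd				u	m	N15
3mbe				2	m	21.30
1u3h				2	m	TCR172.10
3c60				2	m	YAe62
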