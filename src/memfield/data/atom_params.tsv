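# Per-atom parameters: united heavy-atom partial charges and per-atom-type
# water-to-bilayer transfer energies (kcal/mol).  Synthetic, internally
# consistent set anchored to published hydrophobicity-scale orderings;
# substitute force-field charges for production use.
# NTER/CTER rows are terminal patches overriding the base residue rows.
residue	atom_name	atom_type	charge_e	dG_wl_atom
ALA	N	Nbb	-0.300	0.30
ALA	CA	CAbb	0.300	-0.20
ALA	C	Cbb	0.450	-0.15
ALA	O	Obb	-0.450	0.35
ALA	CB	CH3	0.000	-0.90
ARG	N	Nbb	-0.300	0.30
ARG	CA	CAbb	0.300	-0.20
ARG	C	Cbb	0.450	-0.15
ARG	O	Obb	-0.450	0.35
ARG	CB	CH2	0.000	-0.60
ARG	CG	CH2	0.000	-0.60
ARG	CD	CH2	0.000	-0.60
ARG	NE	Narg	0.100	1.30
ARG	CZ	CNH2	0.600	-0.10
ARG	NH1	Narg	0.150	1.30
ARG	NH2	Narg	0.150	1.30
ASH	N	Nbb	-0.300	0.30
ASH	CA	CAbb	0.300	-0.20
ASH	C	Cbb	0.450	-0.15
ASH	O	Obb	-0.450	0.35
ASH	CB	CH2	0.400	-0.60
ASH	CG	CNH2	0.550	-0.10
ASH	OD1	ONH2	-0.550	0.90
ASH	OD2	OH	-0.400	0.80
ASN	N	Nbb	-0.300	0.30
ASN	CA	CAbb	0.300	-0.20
ASN	C	Cbb	0.450	-0.15
ASN	O	Obb	-0.450	0.35
ASN	CB	CH2	0.300	-0.60
ASN	CG	CNH2	0.550	-0.10
ASN	OD1	ONH2	-0.550	0.90
ASN	ND2	NH2O	-0.300	0.90
ASP	N	Nbb	-0.300	0.30
ASP	CA	CAbb	0.300	-0.20
ASP	C	Cbb	0.450	-0.15
ASP	O	Obb	-0.450	0.35
ASP	CB	CH2	-0.160	-0.60
ASP	CG	COO	0.360	0.60
ASP	OD1	OOC	-0.600	1.30
ASP	OD2	OOC	-0.600	1.30
CYS	N	Nbb	-0.300	0.30
CYS	CA	CAbb	0.300	-0.20
CYS	C	Cbb	0.450	-0.15
CYS	O	Obb	-0.450	0.35
CYS	CB	CH2	0.200	-0.60
CYS	SG	S	-0.200	-0.30
GLH	N	Nbb	-0.300	0.30
GLH	CA	CAbb	0.300	-0.20
GLH	C	Cbb	0.450	-0.15
GLH	O	Obb	-0.450	0.35
GLH	CB	CH2	0.000	-0.60
GLH	CG	CH2	0.400	-0.60
GLH	CD	CNH2	0.550	-0.10
GLH	OE1	ONH2	-0.550	0.90
GLH	OE2	OH	-0.400	0.80
GLN	N	Nbb	-0.300	0.30
GLN	CA	CAbb	0.300	-0.20
GLN	C	Cbb	0.450	-0.15
GLN	O	Obb	-0.450	0.35
GLN	CB	CH2	0.000	-0.60
GLN	CG	CH2	0.300	-0.60
GLN	CD	CNH2	0.550	-0.10
GLN	OE1	ONH2	-0.550	0.90
GLN	NE2	NH2O	-0.300	0.90
GLU	N	Nbb	-0.300	0.30
GLU	CA	CAbb	0.300	-0.20
GLU	C	Cbb	0.450	-0.15
GLU	O	Obb	-0.450	0.35
GLU	CB	CH2	0.000	-0.60
GLU	CG	CH2	-0.160	-0.60
GLU	CD	COO	0.360	0.60
GLU	OE1	OOC	-0.600	1.30
GLU	OE2	OOC	-0.600	1.30
GLY	N	Nbb	-0.300	0.30
GLY	CA	CAbb	0.300	-0.20
GLY	C	Cbb	0.450	-0.15
GLY	O	Obb	-0.450	0.35
HIS	N	Nbb	-0.300	0.30
HIS	CA	CAbb	0.300	-0.20
HIS	C	Cbb	0.450	-0.15
HIS	O	Obb	-0.450	0.35
HIS	CB	CH2	0.000	-0.60
HIS	CG	aroC	0.200	-0.40
HIS	ND1	Nhis	-0.350	1.20
HIS	CD2	aroC	0.250	-0.40
HIS	CE1	aroC	0.250	-0.40
HIS	NE2	Nhis	-0.350	1.20
ILE	N	Nbb	-0.300	0.30
ILE	CA	CAbb	0.300	-0.20
ILE	C	Cbb	0.450	-0.15
ILE	O	Obb	-0.450	0.35
ILE	CB	CH1	0.000	-0.35
ILE	CG1	CH2	0.000	-0.60
ILE	CG2	CH3	0.000	-0.90
ILE	CD1	CH3	0.000	-0.90
LEU	N	Nbb	-0.300	0.30
LEU	CA	CAbb	0.300	-0.20
LEU	C	Cbb	0.450	-0.15
LEU	O	Obb	-0.450	0.35
LEU	CB	CH2	0.000	-0.60
LEU	CG	CH1	0.000	-0.35
LEU	CD1	CH3	0.000	-0.90
LEU	CD2	CH3	0.000	-0.90
LYS	N	Nbb	-0.300	0.30
LYS	CA	CAbb	0.300	-0.20
LYS	C	Cbb	0.450	-0.15
LYS	O	Obb	-0.450	0.35
LYS	CB	CH2	0.000	-0.60
LYS	CG	CH2	0.000	-0.60
LYS	CD	CH2	0.000	-0.60
LYS	CE	CH2	0.300	-0.60
LYS	NZ	Nlys	0.700	4.20
MET	N	Nbb	-0.300	0.30
MET	CA	CAbb	0.300	-0.20
MET	C	Cbb	0.450	-0.15
MET	O	Obb	-0.450	0.35
MET	CB	CH2	0.000	-0.60
MET	CG	CH2	0.100	-0.60
MET	SD	S	-0.200	-0.30
MET	CE	CH3	0.100	-0.90
PHE	N	Nbb	-0.300	0.30
PHE	CA	CAbb	0.300	-0.20
PHE	C	Cbb	0.450	-0.15
PHE	O	Obb	-0.450	0.35
PHE	CB	CH2	0.000	-0.60
PHE	CG	aroC	0.000	-0.40
PHE	CD1	aroC	0.000	-0.40
PHE	CD2	aroC	0.000	-0.40
PHE	CE1	aroC	0.000	-0.40
PHE	CE2	aroC	0.000	-0.40
PHE	CZ	aroC	0.000	-0.40
PRO	N	Npro	-0.300	0.10
PRO	CA	CAbb	0.300	-0.20
PRO	C	Cbb	0.450	-0.15
PRO	O	Obb	-0.450	0.35
PRO	CB	CH2	0.000	-0.60
PRO	CG	CH2	0.000	-0.60
PRO	CD	CH2	0.000	-0.60
SER	N	Nbb	-0.300	0.30
SER	CA	CAbb	0.300	-0.20
SER	C	Cbb	0.450	-0.15
SER	O	Obb	-0.450	0.35
SER	CB	CH2	0.400	-0.60
SER	OG	OH	-0.400	0.80
THR	N	Nbb	-0.300	0.30
THR	CA	CAbb	0.300	-0.20
THR	C	Cbb	0.450	-0.15
THR	O	Obb	-0.450	0.35
THR	CB	CH1	0.400	-0.35
THR	OG1	OH	-0.400	0.80
THR	CG2	CH3	0.000	-0.90
TRP	N	Nbb	-0.300	0.30
TRP	CA	CAbb	0.300	-0.20
TRP	C	Cbb	0.450	-0.15
TRP	O	Obb	-0.450	0.35
TRP	CB	CH2	0.000	-0.60
TRP	CG	aroC	0.000	-0.40
TRP	CD1	aroC	0.075	-0.40
TRP	CD2	aroC	0.000	-0.40
TRP	NE1	Ntrp	-0.150	1.00
TRP	CE2	aroC	0.075	-0.40
TRP	CE3	aroC	0.000	-0.40
TRP	CZ2	aroC	0.000	-0.40
TRP	CZ3	aroC	0.000	-0.40
TRP	CH2	aroC	0.000	-0.40
TYR	N	Nbb	-0.300	0.30
TYR	CA	CAbb	0.300	-0.20
TYR	C	Cbb	0.450	-0.15
TYR	O	Obb	-0.450	0.35
TYR	CB	CH2	0.000	-0.60
TYR	CG	aroC	0.000	-0.40
TYR	CD1	aroC	0.000	-0.40
TYR	CD2	aroC	0.000	-0.40
TYR	CE1	aroC	0.000	-0.40
TYR	CE2	aroC	0.000	-0.40
TYR	CZ	aroC	0.400	-0.40
TYR	OH	OH	-0.400	0.80
VAL	N	Nbb	-0.300	0.30
VAL	CA	CAbb	0.300	-0.20
VAL	C	Cbb	0.450	-0.15
VAL	O	Obb	-0.450	0.35
VAL	CB	CH1	0.000	-0.35
VAL	CG1	CH3	0.000	-0.90
VAL	CG2	CH3	0.000	-0.90
NTER	N	Nterm	0.700	3.00
CTER	C	COO	0.450	0.60
CTER	O	OOC	-0.725	1.30
CTER	OXT	OOC	-0.725	1.30
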