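# RNA/RNA nearest-neighbor helix stack free energies, 37 degC, kcal/mol.
# Source: Turner 2004 parameter set (Mathews et al. 2004, PNAS 101:7287;
# Xia et al. 1998, Biochemistry 37:14719 for Watson-Crick stacks), as
# tabulated in the ViennaRNA 2.x distribution file rna_turner2004.par
# (values there are in 0.01 kcal/mol; converted here).
# Entry [row p1][col p2] is the stack 5'-X1 X2-3' / 3'-Y1 Y2-5' with
# p1 = (X1,Y1) and p2 = (Y2,X2); the matrix is symmetric under exchange
# of p1 and p2 (reading the duplex from the opposite strand).
# G.U wobble pairs included; some G.U-on-G.U stacks are destabilizing (>0).
# Duplex initiation: +4.10 kcal/mol (applied once per duplex, not listed
# in this matrix).
pair	CG	GC	GU	UG	AU	UA
CG	-2.40	-3.30	-2.10	-1.40	-2.10	-2.10
GC	-3.30	-3.40	-2.50	-1.50	-2.20	-2.40
GU	-2.10	-2.50	1.30	-0.50	-1.40	-1.30
UG	-1.40	-1.50	-0.50	0.30	-0.60	-1.00
AU	-2.10	-2.20	-1.40	-0.60	-1.10	-0.90
UA	-2.10	-2.40	-1.30	-1.00	-0.90	-1.30
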