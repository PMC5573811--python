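# Degenerate TPS motif library. Pattern notation: fixed residues, (A/B) alternations,
# X wildcard, X<n> fixed-length wildcard run.
name	subfamily	pattern
RRX8W	generic	RRX8W
RDR	generic	R(D/N)R
DDXXD	generic	DDXXD
NSE/DTE	generic	(D/N)D(V/M/L/I)X(S/T)XXXE
RRX8W	tps-a	R(P/R)X(A/S)X(F/Y)HP(S/T/N)(I/L)W
RDR	tps-a	R(D/N)R
DDXXD	tps-a	DD(I/T)(Y/F)D
NSE/DTE	tps-a	(D/N)D(I/M/V)X(S/T/G)(H/Y)(K/E)(F/V)E
RRX8W	tps-b	R(R/Q)SA(N/D)YXP(S/T/N)IW
RDR	tps-b	R(D/N)(R/S)
DDXXD	tps-b	DD(I/V)YD
NSE/DTE	tps-b	(D/N)DL(G/A)TSSDE
DDXXD	tps-g	DDIFD
NSE/DTE	tps-g	DDLGSAKDE
DXDD	tps-c	DXDD
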