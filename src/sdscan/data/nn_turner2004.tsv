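# Nearest-neighbor RNA/RNA helix parameters, Turner 2004 set
# (Watson-Crick stacks after Xia et al. 1998; G.U stacks after Mathews et al. 1999,
# as revised in the Turner 2004 compilation). Free energies are Delta-G at 37 C in
# kcal/mol. Stack keys read 5'-x1 x2-3' over 3'-y1 y2-5' with x1.y1 and x2.y2 paired.
# version: turner2004-1.0
#key	value
init	4.09
terminal_au	0.45
stack:CC/GG	-3.30
stack:CG/GC	-2.40
stack:CG/GU	-1.40
stack:CU/GG	-2.10
stack:CA/GU	-2.10
stack:CU/GA	-2.10
stack:GC/CG	-3.40
stack:GG/CC	-3.30
stack:GG/CU	-1.50
stack:GU/CG	-2.50
stack:GA/CU	-2.40
stack:GU/CA	-2.20
stack:GC/UG	-2.50
stack:GG/UC	-2.10
stack:GG/UU	-0.50
stack:GU/UG	1.30
stack:GA/UU	-1.30
stack:GU/UA	-1.40
stack:UC/GG	-1.50
stack:UG/GC	-1.40
stack:UG/GU	0.30
stack:UU/GG	-0.50
stack:UA/GU	-1.00
stack:UU/GA	-0.60
stack:AC/UG	-2.20
stack:AG/UC	-2.10
stack:AG/UU	-0.60
stack:AU/UG	-1.40
stack:AA/UU	-0.90
stack:AU/UA	-1.10
stack:UC/AG	-2.40
stack:UG/AC	-2.10
stack:UG/AU	-1.00
stack:UU/AG	-1.30
stack:UA/AU	-1.30
stack:UU/AA	-0.90
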