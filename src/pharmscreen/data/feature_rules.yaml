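# Pharmacophore feature perception rules (Catalyst-style conventions).
#
# HBA: N/O bearing an available lone pair and no positive charge; amide and
#      anilinic nitrogens are excluded (delocalized lone pair).
# HBD: N-H / O-H (matched on the heavy atom; implicit hydrogens count).
# HY:  nonpolar carbon atom definition; contiguous components of >= hy_min_atoms
#      such atoms are collapsed to a single centroid feature.
# AR:  aromatic rings, taken from ring perception (no SMARTS needed).
version: 1
hy_min_atoms: 3
patterns:
  HBA:
    - "[O;X2;!$(O=*);!$([O-])]"          # ether / hydroxyl oxygen
    - "[O;X1;$(O=[C,S,P,N])]"            # carbonyl-type oxygen
    - "[n;X2;!$([n+])]"                  # pyridine-type aromatic nitrogen
    - "[N;X1]"                           # nitrile nitrogen
    - "[N;X2;!$([N+]);$(N=*)]"           # imine nitrogen
    - "[N;X3;!$([N+]);!$(N-C=O);!$(N-S=O);!$(N-c);!$(N=*)]"  # amine (not amide/sulfonamide/aniline)
  HBD:
    - "[N;!H0;!$([N+])]"
    - "[O;!H0]"
    - "[n;!H0]"
  HY:
    - "[C;!a;!$(C~[#7,#8,#9,#16,#15,Cl,Br,I])]"
exclude: []
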