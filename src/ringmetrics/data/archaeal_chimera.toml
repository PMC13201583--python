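# Anchor residues for the archaeal Sso-Pf chimeric MCM homohexamer.
#
# The "archaeal" table uses the numbering of the deposited coordinate
# files (Pf residues offset by +1000); "archaeal_construct" carries the
# same anchors in native construct numbering.  All six ring subunits are
# identical, so a single subunit entry serves every ring position.

ring = ["archaeal", "archaeal", "archaeal", "archaeal", "archaeal", "archaeal"]

[subunits.archaeal]
walkerA_pro = 1330        # conserved Walker-A P-loop proline (Pf P330)
argfinger_minus4 = 1824   # 4 residues before the arginine finger (Pf T824)
h2i_leu = 1361            # conserved leucine of the h2i helix/horseshoe region (Pf L361)
ps1b_lys = 1785           # conserved ps1beta hairpin lysine (Pf K785)
ob_anchor = 201           # N-tier dihedral anchor (Sso P201)
aaa_anchor = 1755         # C-tier dihedral anchor (Pf Y755)
h2i_hydroxyl = 1357       # DNA-binding hydroxyl side chain (Pf S357)
h2i_amide = 1732          # DNA-binding main-chain amide (Pf A732)
ps1b_amide = 1786         # DNA-binding main-chain amide (Pf A786)
ob_ranges = [[105, 130], [185, 265]]      # 107-residue OB-fold
core_ranges = [[1319, 1361], [1729, 1837]]  # 152-residue ATPase core

[subunits.archaeal_construct]
walkerA_pro = 330
argfinger_minus4 = 824
h2i_leu = 361
ps1b_lys = 785
ob_anchor = 201
aaa_anchor = 755
h2i_hydroxyl = 357
h2i_amide = 732
ps1b_amide = 786
ob_ranges = [[105, 130], [185, 265]]
core_ranges = [[319, 361], [729, 837]]
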