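# Interface anchor residues for S. cerevisiae Mcm2-7.
#
# Per subunit: the Walker-A-side anchors (walkerA_pro, h2i_leu) are used
# when the subunit sits on the Walker-A side of an interface; the
# arginine-finger-side anchors (argfinger_minus4, ps1b_lys) when it sits
# on the neighbouring side.  OB/core residue ranges for the 152-aa
# ATPase core are not shipped for eukaryotes and must be supplied by the
# user for setting-RMSD or direct dihedral runs.

ring = ["Mcm2", "Mcm6", "Mcm4", "Mcm7", "Mcm3", "Mcm5"]

[subunits.Mcm2]
walkerA_pro = 545
argfinger_minus4 = 672
h2i_leu = 576
ps1b_lys = 633

[subunits.Mcm6]
walkerA_pro = 577
argfinger_minus4 = 704
h2i_leu = 608
ps1b_lys = 665

[subunits.Mcm4]
walkerA_pro = 570
argfinger_minus4 = 697
h2i_leu = 601
ps1b_lys = 658

[subunits.Mcm7]
walkerA_pro = 462
argfinger_minus4 = 589
h2i_leu = 493
ps1b_lys = 550

[subunits.Mcm3]
walkerA_pro = 411
argfinger_minus4 = 538
h2i_leu = 442
ps1b_lys = 499

[subunits.Mcm5]
walkerA_pro = 418
argfinger_minus4 = 545
h2i_leu = 449
ps1b_lys = 506
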