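# Interface anchor residues for human Mcm2-7 (layout as in sc_mcm2_7.toml).

ring = ["Mcm2", "Mcm6", "Mcm4", "Mcm7", "Mcm3", "Mcm5"]

[subunits.Mcm2]
walkerA_pro = 525
argfinger_minus4 = 652
h2i_leu = 556
ps1b_lys = 613

[subunits.Mcm6]
walkerA_pro = 398
argfinger_minus4 = 525
h2i_leu = 429
ps1b_lys = 486

[subunits.Mcm4]
walkerA_pro = 512
argfinger_minus4 = 639
h2i_leu = 543
ps1b_lys = 600

[subunits.Mcm7]
walkerA_pro = 383
argfinger_minus4 = 510
h2i_leu = 414
ps1b_lys = 471

[subunits.Mcm3]
walkerA_pro = 347
argfinger_minus4 = 474
h2i_leu = 378
ps1b_lys = 435

[subunits.Mcm5]
walkerA_pro = 383
argfinger_minus4 = 509
h2i_leu = 414
ps1b_lys = 471
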