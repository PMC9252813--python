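"""Packaged list of small-molecule structures used by the spectrum simulator.

Common metabolites, natural products and drug-like xenobiotics, curated so
every entry parses, is neutral, has a monoisotopic mass below 520 Da and a
molecular formula distinct from every other entry (so simulated libraries
contain no exact-mass ties by construction).
"""

#: (name, canonical SMILES) pairs.
COMPOUNDS = [
    ("glycine", "NCC(=O)O"),
    ("alanine", "CC(N)C(=O)O"),
    ("serine", "NC(CO)C(=O)O"),
    ("proline", "O=C(O)C1CCCN1"),
    ("valine", "CC(C)C(N)C(=O)O"),
    ("threonine", "CC(O)C(N)C(=O)O"),
    ("cysteine", "NC(CS)C(=O)O"),
    ("leucine", "CC(C)CC(N)C(=O)O"),
    ("asparagine", "NC(=O)CC(N)C(=O)O"),
    ("aspartate", "NC(CC(=O)O)C(=O)O"),
    ("glutamine", "NC(=O)CCC(N)C(=O)O"),
    ("lysine", "NCCCCC(N)C(=O)O"),
    ("glutamate", "NC(CCC(=O)O)C(=O)O"),
    ("methionine", "CSCCC(N)C(=O)O"),
    ("histidine", "NC(Cc1c[nH]cn1)C(=O)O"),
    ("phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
    ("arginine", "N=C(N)NCCCC(N)C(=O)O"),
    ("tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
    ("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(=O)O"),
    ("formate", "O=CO"),
    ("acetate", "CC(=O)O"),
    ("propionate", "CCC(=O)O"),
    ("butyrate", "CCCC(=O)O"),
    ("lactate", "CC(O)C(=O)O"),
    ("pyruvate", "CC(=O)C(=O)O"),
    ("oxaloacetate", "O=C(O)CC(=O)C(=O)O"),
    ("succinate", "O=C(O)CCC(=O)O"),
    ("fumarate", "O=C(O)/C=C/C(=O)O"),
    ("malate", "O=C(O)CC(O)C(=O)O"),
    ("citrate", "O=C(O)CC(O)(CC(=O)O)C(=O)O"),
    ("alpha-ketoglutarate", "O=C(O)CCC(=O)C(=O)O"),
    ("glycolate", "O=C(O)CO"),
    ("glyoxylate", "O=CC(=O)O"),
    ("oxalate", "O=C(O)C(=O)O"),
    ("malonate", "O=C(O)CC(=O)O"),
    ("glutarate", "O=C(O)CCCC(=O)O"),
    ("adipate", "O=C(O)CCCCC(=O)O"),
    ("benzoate", "O=C(O)c1ccccc1"),
    ("salicylate", "O=C(O)c1ccccc1O"),
    ("hippurate", "O=C(O)CNC(=O)c1ccccc1"),
    ("vanillate", "COc1cc(C(=O)O)ccc1O"),
    ("caffeate", "O=C(O)/C=C/c1ccc(O)c(O)c1"),
    ("ferulate", "COc1cc(/C=C/C(=O)O)ccc1O"),
    ("cinnamate", "O=C(O)/C=C/c1ccccc1"),
    ("gallate", "O=C(O)c1cc(O)c(O)c(O)c1"),
    ("citraconate", "CC(=CC(=O)O)C(=O)O"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("ribose", "OCC1OC(O)C(O)C1O"),
    ("erythrose", "O=CC(O)C(O)CO"),
    ("glycerol", "OCC(O)CO"),
    ("erythritol", "OCC(O)C(O)CO"),
    ("ribitol", "OCC(O)C(O)C(O)CO"),
    ("mannitol", "OCC(O)C(O)C(O)C(O)CO"),
    ("sucrose", "OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O"),
    ("glucuronate", "O=C(O)C1OC(O)C(O)C(O)C1O"),
    ("gluconate", "O=C(O)C(O)C(O)C(O)C(O)CO"),
    ("fucose", "CC1OC(O)C(O)C(O)C1O"),
    ("glucosamine", "NC1C(O)OC(CO)C(O)C1O"),
    ("n-acetylglucosamine", "CC(=O)NC1C(O)OC(CO)C(O)C1O"),
    ("uracil", "O=c1cc[nH]c(=O)[nH]1"),
    ("thymine", "Cc1c[nH]c(=O)[nH]c1=O"),
    ("cytosine", "Nc1cc[nH]c(=O)n1"),
    ("adenine", "Nc1ncnc2[nH]cnc12"),
    ("guanine", "Nc1nc2[nH]cnc2c(=O)[nH]1"),
    ("hypoxanthine", "O=c1[nH]cnc2[nH]cnc12"),
    ("xanthine", "O=c1[nH]c(=O)c2[nH]cnc2[nH]1"),
    ("uric acid", "O=c1[nH]c(=O)c2[nH]c(=O)[nH]c2[nH]1"),
    ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
    ("theobromine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
    ("adenosine", "Nc1ncnc2c1ncn2C1OC(CO)C(O)C1O"),
    ("uridine", "O=c1ccn(C2OC(CO)C(O)C2O)c(=O)[nH]1"),
    ("cytidine", "Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1"),
    ("guanosine", "Nc1nc2c(ncn2C2OC(CO)C(O)C2O)c(=O)[nH]1"),
    ("carnitine", "C[N+](C)(C)CC(O)CC(=O)[O-]"),
    ("taurine", "NCCS(=O)(=O)O"),
    ("hypotaurine", "NCCS(=O)O"),
    ("creatine", "CN(CC(=O)O)C(=N)N"),
    ("creatinine", "CN1CC(=O)N=C1N"),
    ("gaba", "NCCCC(=O)O"),
    ("putrescine", "NCCCCN"),
    ("cadaverine", "NCCCCCN"),
    ("spermidine", "NCCCCNCCCN"),
    ("histamine", "NCCc1c[nH]cn1"),
    ("tyramine", "NCCc1ccc(O)cc1"),
    ("dopamine", "NCCc1ccc(O)c(O)c1"),
    ("serotonin", "NCCc1c[nH]c2ccc(O)cc12"),
    ("tryptamine", "NCCc1c[nH]c2ccccc12"),
    ("epinephrine", "CNCC(O)c1ccc(O)c(O)c1"),
    ("phenylethylamine", "NCCc1ccccc1"),
    ("ethanolamine", "NCCO"),
    ("urea", "NC(N)=O"),
    ("guanidine", "N=C(N)N"),
    ("niacin", "O=C(O)c1cccnc1"),
    ("nicotinamide", "NC(=O)c1cccnc1"),
    ("pyridoxine", "Cc1ncc(CO)c(CO)c1O"),
    ("pyridoxal", "Cc1ncc(CO)c(C=O)c1O"),
    ("thiamine-frag", "Cc1ncc(C)c(N)n1"),
    ("pantothenate", "CC(C)(CO)C(O)C(=O)NCCC(=O)O"),
    ("biotin", "O=C(O)CCCCC1SCC2NC(=O)NC21"),
    ("folate-frag", "NCc1cnc2nc(N)[nH]c(=O)c2n1"),
    ("caproate", "CCCCCC(=O)O"),
    ("caprylate", "CCCCCCCC(=O)O"),
    ("caprate", "CCCCCCCCCC(=O)O"),
    ("laurate", "CCCCCCCCCCCC(=O)O"),
    ("myristate", "CCCCCCCCCCCCCC(=O)O"),
    ("palmitate", "CCCCCCCCCCCCCCCC(=O)O"),
    ("stearate", "CCCCCCCCCCCCCCCCCC(=O)O"),
    ("oleate", r"CCCCCCCC/C=C\CCCCCCCC(=O)O"),
    ("linoleate", r"CCCCC/C=C\C/C=C\CCCCCCCC(=O)O"),
    ("glycerophosphocholine-frag", "O=P(O)(O)OCC(O)CO"),
    ("phosphoenolpyruvate", "C=C(OP(=O)(O)O)C(=O)O"),
    ("g6p", "O=P(O)(O)OCC1OC(O)C(O)C(O)C1O"),
    ("amp", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1"),
    ("sulfanilamide", "Nc1ccc(S(N)(=O)=O)cc1"),
    ("coumarin", "O=c1ccc2ccccc2o1"),
    ("umbelliferone", "O=c1ccc2ccc(O)cc2o1"),
    ("quercetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12"),
    ("naringenin", "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21"),
    ("resveratrol", "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1"),
    ("vanillin", "COc1cc(C=O)ccc1O"),
    ("menthol", "CC1CCC(C(C)C)C(O)C1"),
    ("camphor", "CC12CCC(CC1=O)C2(C)C"),
    ("limonene", "C=C(C)C1CC=C(C)CC1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("indole-3-acetate", "O=C(O)Cc1c[nH]c2ccccc12"),
    ("kynurenine", "Nc1ccccc1C(=O)CC(N)C(=O)O"),
    ("melatonin", "COc1ccc2[nH]cc(CCNC(C)=O)c2c1"),
    ("cortisol-frag", "CC12CCC(=O)C=C1CCC1C(O)CCC12"),
    ("cholesterol-frag", "CC(C)CCCC(C)C1CCC2C1CCC1C2CC=C2CC(O)CCC21C"),
    ("chlorogenate", "O=C(/C=C/c1ccc(O)c(O)c1)OC1C(O)CC(O)(C(=O)O)CC1O"),
    ("shikimate", "O=C(O)C1=CC(O)C(O)C(O)C1"),
    ("quinate", "O=C(O)C1(O)CC(O)C(O)C(O)C1"),
    ("trigonelline", "C[n+]1cccc(C(=O)[O-])c1"),
    ("2-furoate", "O=C(O)c1ccco1"),
    ("phenylacetate", "O=C(O)Cc1ccccc1"),
    ("phenyllactate", "O=C(O)C(O)Cc1ccccc1"),
    ("p-cresol", "Cc1ccc(O)cc1"),
    ("catechol", "Oc1ccccc1O"),
    ("hydroquinone-mono", "COc1ccc(O)cc1"),
    ("4-chlorobenzoate", "O=C(O)c1ccc(Cl)cc1"),
    ("4-fluorophenol", "Oc1ccc(F)cc1"),
    ("2-bromophenol", "Oc1ccccc1Br"),
    ("triclosan-frag", "Oc1cc(Cl)ccc1Oc1ccc(Cl)cc1Cl"),
]
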