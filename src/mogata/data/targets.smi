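# Reference structures for the built-in multi-property optimization benchmarks.
# Provenance: marketed-drug structures as distributed with the GuacaMol goal-directed
# benchmark suite (canonicalized with RDKit). One record per line: SMILES name.
CC(C)(C(=O)O)c1ccc(C(O)CCCN2CCC(C(O)(c3ccccc3)c3ccccc3)CC2)cc1 fexofenadine
CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1 pioglitazone
C=CC(=O)Nc1cc(Nc2nccc(-c3cn(C)c4ccccc34)n2)c(OC)cc1N(C)CCN(C)C osimertinib
COc1ccccc1OCC(O)CN1CCN(CC(=O)Nc2c(C)cccc2C)CC1 ranolazine
OC1(C2CCCCN2)CN(C(=O)c2ccc(F)c(F)c2Nc2ccc(I)cc2F)C1 cobimetinib
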