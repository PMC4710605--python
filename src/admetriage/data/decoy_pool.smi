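Cn1cnc2c1c(=O)n(C)c(=O)n2C caffeine
OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O glucose
CC(=O)Oc1ccccc1C(=O)O aspirin
CC(C)Cc1ccc(C(C)C(=O)O)cc1 ibuprofen
c1ccc2ccccc2c1 naphthalene
c1ccc2cc3ccccc3cc2c1 anthracene
CC(=C)C1CCC(C)=CC1 limonene
COc1cc(C=O)ccc1O vanillin
NCCc1c[nH]c2ccc(O)cc12 serotonin
NCCc1ccc(O)c(O)c1 dopamine
CN1CCC[C@H]1c1cccnc1 nicotine
c1ccc2ncccc2c1 quinoline
c1ccc2[nH]ccc2c1 indole
c1ccncc1 pyridine
c1c[nH]cn1 imidazole
Cc1ccccc1 toluene
Oc1ccccc1 phenol
O=C(O)c1ccccc1 benzoic-acid
C1CCCCC1 cyclohexane
CCCCCC hexane
CCCCCCCCO octanol
OCC(O)CO glycerol
OC(=O)CC(O)(C(=O)O)CC(=O)O citric-acid
NC(N)=O urea
C[C@H](N)C(=O)O alanine
N[C@@H](Cc1ccccc1)C(=O)O phenylalanine
N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O tryptophan
Nc1ncnc2[nH]cnc12 adenine
Nc1nc2[nH]cnc2c(=O)[nH]1 guanine
Cc1c[nH]c(=O)[nH]c1=O thymine
O=c1cc[nH]c(=O)[nH]1 uracil
Nc1cc[nH]c(=O)n1 cytosine
CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O menthol
CC1(C)C2CCC1(C)C(=O)C2 camphor
C=CCc1ccc(O)c(OC)c1 eugenol
O=C/C=C/c1ccccc1 cinnamaldehyde
O=c1ccc2ccccc2o1 coumarin
Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1 resveratrol
CC12CCC3C(CCc4cc(O)ccc43)C1CCC2O estradiol-framework
CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O testosterone-framework
OCCO ethylene-glycol
CC(C)=O acetone
CS(C)=O dimethylsulfoxide
c1ccc2[nH]cnc2c1 benzimidazole
C1CCNCC1 piperidine
C1COCCN1 morpholine
c1ccoc1 furan
c1ccsc1 thiophene
c1cc2ccc3cccc4ccc(c1)c2c34 pyrene
c1ccc(-c2ccccc2)cc1 biphenyl
O(c1ccccc1)c1ccccc1 diphenyl-ether
O=C(c1ccccc1)c1ccccc1 benzophenone
CCCCCCCCCCCCCCCCCC(=O)O stearic-acid
CCO ethanol
CC(O)=O acetic-acid
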