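id,name,smiles,assay_outcome,ac50_uM,exposure_category,metabolism_code,parent_id,absorption_annotation,distribution_annotation,promiscuity_override,registry_casrn
chlorpyrifos,Chlorpyrifos,CCOP(=S)(OCC)Oc1nc(Cl)c(Cl)cc1Cl,inactive,,1,+,,,,,2921-88-2
chlorpyrifos-methyl,Chlorpyrifos methyl,COP(=S)(OC)Oc1nc(Cl)c(Cl)cc1Cl,inactive,,1,+,,,,,5598-13-0
dichlorvos,Dichlorvos,COP(=O)(OC)OC=C(Cl)Cl,inactive,,1,-,naled,,,,62-73-7
aldicarb,Aldicarb,CNC(=O)O/N=C/C(C)(C)SC,inactive,,1,,,,,,116-06-3
trichlorfon,Trichlorfon,COP(=O)(OC)C(O)C(Cl)(Cl)Cl,inactive,,1,,,,,,52-68-6
phosalone,Phosalone,CCOP(=S)(OCC)SCN1C(=O)Oc2cc(Cl)ccc21,inactive,,1,,,,,,2310-17-0
malaoxon,Malaoxon,CCOC(=O)CC(SP(=O)(OC)OC)C(=O)OCC,inactive,,1,,,,,,1634-78-2
zamifenacin,Zamifenacin,O1COc2cc(CCN3CCC[C@@H](COC(c4ccccc4)c4ccccc4)C3)ccc12,inactive,,2,,,,,,127308-98-9
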