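id,name,smiles,assay_outcome,ac50_uM,exposure_category,metabolism_code,parent_id,absorption_annotation,distribution_annotation,promiscuity_override,registry_casrn
chlorpyrifos-oxon,Chlorpyrifos oxon,CCOP(=O)(OCC)Oc1nc(Cl)c(Cl)cc1Cl,active,0.149,1,+,chlorpyrifos,Yes,Yes,,5598-15-2
pharmagsid-47259,PharmaGSID_47259,,active,0.287,4,-,,NA,NA,,
carbofuran,Carbofuran,CNC(=O)Oc1cccc2c1OC(C)(C)C2,active,0.416,3,+/-,carbosulfan,Yes,Yes,,1563-66-2
anthralin,Anthralin,O=C1c2cccc(O)c2Cc2cccc(O)c21,active,0.512,2,-,,Yes,No,,1143-38-0
naled,Naled,COP(=O)(OC)OC(Br)C(Cl)(Cl)Br,active,1.01,1,-,,Yes,Yes,,300-76-5
carbosulfan,Carbosulfan,CCCCN(CCCC)SN(C)C(=O)Oc1cccc2c1OC(C)(C)C2,active,1.21,1,+/-,,Limited,Yes,,55285-14-8
raloxifene-hydrochloride,Raloxifene hydrochloride,Oc1ccc(-c2sc3cc(O)ccc3c2C(=O)c2ccc(OCCN3CCCCC3)cc2)cc1.Cl,active,1.85,2,-,,Limited,No,,82640-04-8
1-benzylquinolinium-chloride,1-Benzylquinolinium chloride,[Cl-].C(c1ccccc1)[n+]1cccc2ccccc21,active,2.48,2,U,,Yes,Yes,true,15619-48-4
besonprodil,Besonprodil,,active,3.49,3,-,,Yes,Yes,,253450-09-8
bendiocarb,Bendiocarb,CNC(=O)Oc1cccc2c1OC(C)(C)O2,active,4.09,3,-,,Yes,Yes,,22781-23-3
sb236057a,SB236057A,,active,4.63,4,-,,NA,NA,,
gw473178e,GW473178E,,active,4.79,4,-,,NA,NA,,
ssr241586,SSR241586,,active,4.86,3,-,,Limited,Yes,,
ssr69071,SSR69071,,active,5.05,4,-,,NA,NA,,
mevinphos,Mevinphos,COP(=O)(OC)O/C(C)=C/C(=O)OC,active,5.11,3,+/-,,Yes,Yes,,7786-34-7
azamethiphos,Azamethiphos,COP(=O)(OC)SCN1C(=O)Oc2cc(Cl)cnc21,active,6.6,2,+/-,,Yes,Yes,,35575-96-3
oxamyl,Oxamyl,CNC(=O)O/N=C(\SC)C(=O)N(C)C,active,7.4,2,-,,Yes,Yes,,23135-22-0
gentian-violet,Gentian violet,[Cl-].CN(C)c1ccc(C(=C2C=CC(=[N+](C)C)C=C2)c2ccc(N(C)C)cc2)cc1,active,7.65,1,+,,Yes,Yes,true,548-62-9
toluene-24-diisocyanate,"Toluene-2,4-diisocyanate",Cc1ccc(N=C=O)cc1N=C=O,active,8.78,2,+/-,,Yes,Yes,,584-84-9
didecyldimethylammonium-chloride,Didecyldimethylammonium chloride,[Cl-].CCCCCCCCCC[N+](C)(C)CCCCCCCCCC,active,12.1,1,-,,Limited,Yes,,7173-51-5
propoxur,Propoxur,CNC(=O)Oc1ccccc1OC(C)C,active,12.7,1,+/-,,Yes,Yes,,114-26-1
methomyl,Methomyl,CNC(=O)O/N=C(\C)SC,active,13.9,3,-,,Yes,Yes,,16752-77-5
pentamidine-isethionate,Pentamidine isethionate,N=C(N)c1ccc(OCCCCCOc2ccc(C(=N)N)cc2)cc1.OCCS(=O)(=O)O.OCCS(=O)(=O)O,active,16.8,2,NA,,Limited,No,,140-64-7
bis2-ethylhexyl-decanedioate,bis(2-Ethylhexyl) decanedioate,CCCCC(CC)COC(=O)CCCCCCCCC(=O)OCC(CC)CCCC,active,17,4,=,,NA,NA,,122-62-3
sr125047,SR125047,,active,17.6,4,-,,NA,NA,,
pharmagsid-48172,PharmaGSID_48172,,active,18.3,4,-,,NA,NA,,
dodecylbenzenesulfonic-acid,Dodecylbenzenesulfonic acid,CCCCCCCCCCCCc1ccc(S(=O)(=O)O)cc1,active,19.3,1,+/-,,Limited,Yes,,27176-87-0
ssr150106,SSR150106,,active,20.9,3,+,,Yes,Yes,,
mercuric-chloride,Mercuric chloride,Cl[Hg]Cl,active,23.1,2,+,,Yes,Yes,,7487-94-7
bronopol,Bronopol,OCC(Br)(CO)[N+](=O)[O-],active,23.3,1,+/-,,Yes,Yes,,52-51-7
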