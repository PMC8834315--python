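compound_id,name,smiles,binding_energy,binding_efficiency,role
DB00378,Dydrogesterone,CC(=O)[C@@H]1CC[C@H]2[C@@H]3C=CC4=CC(=O)CC[C@@]4(C)[C@@H]3CC[C@]12C,-12.6,-0.548,candidate
DB06710,Methyltestosterone,C[C@]12CC[C@H]3[C@@H](CCC4=CC(=O)CC[C@]34C)[C@@H]1CC[C@@]2(C)O,-11.6,-0.527,candidate
DB04575,Quinestrol,C#C[C@]1(O)CC[C@H]2[C@@H]3CCc4cc(OC5CCCC5)ccc4[C@H]3CC[C@]12C,-11.6,-0.43,candidate
DB09280,Lumacaftor,Cc1ccc(NC(=O)C2(c3ccc4c(c3)OC(F)(F)O4)CC2)nc1-c1cccc(C(=O)O)c1,-12.1,-0.367,candidate
DB00984,Nandrolone phenpropionate,O=C(CCc1ccccc1)O[C@H]1CC[C@H]2[C@@H]3CCC4=CC(=O)CC[C@H]4[C@H]3CC[C@]12C,-11.6,-0.387,candidate
DB05812,Abiraterone,C[C@]12CC[C@H]3[C@@H](CC=C4C[C@@H](O)CC[C@]34C)[C@@H]1CC=C2c1cccnc1,-11.4,-0.438,candidate
DB06210,Eltrombopag,Cc1ccc(N2N=C(C)/C(=N\Nc3ccc(-c4cccc(C(=O)O)c4)cc3O)C2=O)cc1C,-11.4,-0.345,candidate
DB00977,Ethinyl Estradiol,C#C[C@]1(O)CC[C@H]2[C@@H]3CCc4cc(O)ccc4[C@H]3CC[C@]12C,-11.3,-0.514,candidate
DB01420,Testosterone propionate,CCC(=O)O[C@H]1CC[C@H]2[C@@H]3CCC4=CC(=O)CC[C@]4(C)[C@H]3CC[C@]12C,-11.3,-0.452,candidate
DB12598,Nafamostat,N=C(N)c1ccc2cc(OC(=O)c3ccc(NC(=N)N)cc3)ccc2c1,-11.3,-0.435,candidate
DB04540,Cholesterol,CC(C)CCC[C@@H](C)[C@H]1CC[C@H]2[C@@H]3CC=C4C[C@@H](O)CC[C@]4(C)[C@H]3CC[C@]12C,-11.3,-0.404,reference
DB04705,25-Hydroxycholesterol,CC(CCCC(C)(C)O)[C@H]1CC[C@H]2[C@@H]3CC=C4C[C@@H](O)CC[C@]4(C)[C@H]3CC[C@]12C,-11.7,-0.403,reference
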