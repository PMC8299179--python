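compound_id,smiles,percent_inhibition
polmacoxib,CC1(C)OC(=O)C(c2ccc(S(N)(=O)=O)cc2)=C1c1ccc(F)cc1,92
celecoxib,Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1,95
valdecoxib,Cc1onc(-c2ccccc2)c1-c1ccc(S(N)(=O)=O)cc1,90
rofecoxib,O=C1OCC(c2ccccc2)=C1c1ccc(S(C)(=O)=O)cc1,88
parecoxib,CCC(=O)NS(=O)(=O)c1ccc(-c2c(-c3ccccc3)noc2C)cc1,85
deracoxib,COc1ccc(-c2cc(C(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1F,83
mavacoxib,Fc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1,86
etoricoxib,Cc1ccc(-c2ncc(Cl)cc2-c2ccc(S(C)(=O)=O)cc2)cn1,72
lumiracoxib,Cc1ccc(Nc2c(Cl)cccc2F)c(CC(=O)O)c1,48
nimesulide,CS(=O)(=O)Nc1ccc([N+](=O)[O-])cc1Oc1ccccc1,41
diclofenac,O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl,22
aspirin,CC(=O)Oc1ccccc1C(=O)O,8
ibuprofen,CC(C)Cc1ccc(C(C)C(=O)O)cc1,5
naproxen,COc1ccc2cc(C(C)C(=O)O)ccc2c1,11
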