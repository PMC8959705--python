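"""Built-in library of drug-like SMILES used by the synthetic generator.

A broad mix of natural products (flavonoids, coumarins, alkaloids,
terpenoids, phenylpropanoids — the chemistry classes dominating herbal
extracts) and small synthetic drugs. The generator draws structures from
this list and optionally decorates them with small substituents; it makes
no claim that a generated record corresponds to any named real compound.
"""

DRUGLIKE_SMILES: tuple[str, ...] = (
    # simple aromatics, phenols, benzoic/cinnamic acids
    "CC(=O)Oc1ccccc1C(=O)O",
    "Oc1ccccc1C(=O)O",
    "O=C(O)c1ccccc1",
    "O=C(O)c1ccc(O)cc1",
    "O=C(O)c1cc(O)c(O)c(O)c1",
    "COc1cc(C=O)ccc1O",
    "COc1cc(/C=C/C(=O)O)ccc1O",
    "Oc1ccc(/C=C/C(=O)O)cc1O",
    "O=C(O)/C=C/c1ccccc1",
    "Oc1ccc(/C=C/C(=O)O)cc1",
    "COc1cc(/C=C/C(=O)O)cc(OC)c1O",
    "COc1ccc(/C=C/C(=O)O)cc1",
    "Oc1ccc(CCC(=O)O)cc1",
    "COc1cc(C=O)cc(OC)c1O",
    "Oc1ccc(C=O)cc1",
    "Oc1ccc(CO)cc1",
    "COc1ccccc1O",
    "Oc1ccc(CC=C)cc1",
    "COc1cc(CC=C)ccc1O",
    "COc1cc(/C=C/C)ccc1O",
    "Cc1ccc(C(C)C)c(O)c1",
    "Cc1ccc(O)c(C(C)C)c1",
    "Oc1ccc(C(=O)CC(O)c2ccccc2)cc1",
    "Oc1ccccc1/C=C/C(=O)O",
    "COc1ccc(C=O)cc1",
    "Oc1cc(O)cc(/C=C/c2ccc(O)cc2)c1",
    "COc1cc(/C=C/c2ccc(O)cc2)cc(OC)c1",
    "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1O",
    # flavones / flavonols / flavanones / isoflavones
    "Oc1cc(O)c2c(c1)oc(-c1ccccc1)cc2=O",
    "Oc1ccc(-c2cc(=O)c3c(O)cc(O)cc3o2)cc1",
    "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)cc2=O",
    "Oc1ccc(-c2oc3cc(O)cc(O)c3c(=O)c2O)cc1",
    "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O",
    "COc1ccc(-c2cc(=O)c3c(O)cc(O)cc3o2)cc1",
    "Oc1ccc(C2CC(=O)c3c(O)cc(O)cc3O2)cc1",
    "Oc1ccc(C2CC(=O)c3c(O)cc(O)cc3O2)cc1O",
    "COc1ccc(C2CC(=O)c3c(O)cc(O)cc3O2)cc1O",
    "Oc1ccc(-c2coc3cc(O)cc(O)c3c2=O)cc1",
    "Oc1ccc(-c2coc3cc(O)ccc3c2=O)cc1",
    "COc1ccc(-c2coc3cc(O)cc(O)c3c2=O)cc1",
    "Oc1cc(O)c2c(c1)oc(-c1ccc(O)cc1)c(O)c2=O",
    "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1O)c(O)c2=O",
    "COc1cc2oc(-c3ccc(O)cc3)cc(=O)c2c(O)c1OC",
    "Oc1ccc2c(c1)oc(-c1ccccc1)cc2=O",
    "Oc1cc(O)c2c(c1)oc(-c1ccccc1O)cc2=O",
    "CC1CC(=O)c2c(O)cc(O)cc2O1",
    "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2",
    "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2O",
    "Oc1cc(O)c2c(c1)OC(c1cc(O)c(O)c(O)c1)C(O)C2",
    "COc1cc(-c2cc(=O)c3c(O)cc(O)cc3o2)ccc1O",
    "Oc1ccc(-c2cc(=O)c3ccccc3o2)cc1",
    "O=c1cc(-c2ccccc2)oc2ccccc12",
    "Cc1cc(=O)c2c(O)cc(O)cc2o1",
    # coumarins
    "O=c1ccc2ccccc2o1",
    "Oc1ccc2ccc(=O)oc2c1",
    "Oc1cc2oc(=O)ccc2cc1O",
    "COc1cc2ccc(=O)oc2cc1O",
    "COc1ccc2ccc(=O)oc2c1",
    "CC(C)=CCc1c(O)ccc2ccc(=O)oc12",
    "COc1c2occc2cc2ccc(=O)oc12",
    "O=c1ccc2cc3ccoc3cc2o1",
    "CC1(C)Oc2ccc3ccc(=O)oc3c2C1O",
    "COc1cc2oc(=O)ccc2cc1OC",
    # alkaloids and amines
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "Cn1cnc2c1c(=O)[nH]c(=O)n2C",
    "Cn1c(=O)c2[nH]cnc2n(C)c1=O",
    "CN1CCCC1c1cccnc1",
    "CN1CCC2(CC1)Oc1ccc(O)cc1C2",
    "COc1ccc2c(c1)CCN(C)C2Cc1ccc(O)cc1",
    "COc1cc2c(cc1OC)C(Cc1ccc(O)c(O)c1)N(C)CC2",
    "CN(C)CCc1c[nH]c2ccccc12",
    "NCCc1c[nH]c2ccccc12",
    "COc1ccc2[nH]cc(CCN)c2c1",
    "NCCc1ccc(O)c(O)c1",
    "CNCC(O)c1ccc(O)c(O)c1",
    "NCC(O)c1ccc(O)c(O)c1",
    "CNC(C)C(O)c1ccccc1",
    "CC(N)C(O)c1ccccc1",
    "CNC(C)Cc1ccccc1",
    "CC(N)Cc1ccc(O)cc1",
    "CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2",
    "CN1C2CCC1CC(OC(=O)c1ccccc1)C2",
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",
    "CCOC(=O)c1ccc(N)cc1",
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",
    "CN(C)CCOC(c1ccccc1)c1ccccc1",
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",
    "CN(C)CCCN1c2ccccc2Sc2ccccc21",
    "O=C(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "OC(c1ccccc1)(c1ccccc1)C1CCN(C)CC1",
    "COc1ccc2cc3[n+](cc2c1OC)CCc1cc2c(cc1-3)OCO2",
    "Cn1c2ccccc2c2cc(Cl)ccc21",
    "Cn1ccc2cc3c(cc21)OCO3",
    "c1ccc2c(c1)ccc1cccnc12",
    "CC(=O)Nc1ccc(O)cc1",
    "CC(=O)Nc1ccc(OCC)cc1",
    "CN1CCN(c2ccccc2)CC1",
    "O=C1CC(c2ccccc2)NC(=O)N1",
    "CCC1(c2ccccc2)C(=O)NC(=O)NC1=O",
    "CCC1(CC)C(=O)NC(=O)NC1=O",
    "Cn1c(=O)n(C)c2nc[nH]c2c1=O",
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1",
    "Clc1ccccc1C1=NCc2nncn2-c2ccccc21",
    # NSAIDs, profens, simple acids
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "CC(C(=O)O)c1ccc(-c2ccccc2)cc1",
    "CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1",
    "O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl",
    "CC(=O)c1ccc2ccccc2c1O",
    "O=C(O)c1ccccc1Nc1cccc(C(F)(F)F)c1",
    "Cc1ccccc1Nc1ccccc1C(=O)O",
    "O=C(O)c1ccccc1O",
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "O=C(Cc1ccccc1)Nc1ccccc1C(=O)O",
    "O=C(O)COc1ccccc1",
    "O=C(O)CCc1ccccc1",
    # terpenoids and steroids
    "CC(C)C1CCC(C)CC1O",
    "CC1(C)C2CCC1(C)C(=O)C2",
    "CC(=C)C1CCC(C)=CC1",
    "CC1=CCC(C(C)C)CC1O",
    "CC1=CC(=O)C(C(C)C)CC1",
    "CC1CCC(C(C)C)C(O)C1",
    "CC1CCC2(C(=O)O)CCC3(C)C(=CC2C1(C)C)C1CC(C)(C)CCC1(C)CC3O",
    "CC1(C)CCC2(C(=O)O)CCC3(C)C(=CCC4C5(C)CCC(O)C(C)(C)C5CCC43C)C2C1",
    "CC12CCC(=O)C=C1CCC1C2CCC2(C)C1CCC2O",
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2=O",
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",
    "CC12CCC(=O)C=C1CCC1C2CCC2(C)C1CCC2(O)C#C",
    "CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C",
    "CC(C)=CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C",
    "CC1CCC2(C)C(C)C(=O)C=C3C4(C)CCC(O)C(C)(C)C4CCC32C1",
    "CC(=O)OC1CCC2(C)C(=CCC3C2CCC2(C)C3CCC2C(C)=O)C1",
    "OC1CCC2(C)C(CCC3C2CCC2(C)C3CCC2O)C1",
    # glycosides kept small (mono-glycosylated phenolics)
    "OCC1OC(Oc2ccc(O)cc2)C(O)C(O)C1O",
    "OCC1OC(Oc2ccccc2)C(O)C(O)C1O",
    "OCC1OC(Oc2cc(O)cc(O)c2)C(O)C(O)C1O",
    "OCC1OC(Oc2ccc(/C=C/C(=O)O)cc2)C(O)C(O)C1O",
    "OCC1OC(Oc2ccc(CO)cc2)C(O)C(O)C1O",
    "OC1C(O)C(O)C(Oc2cc(O)c3c(c2)oc(-c2ccccc2)cc3=O)OC1C(=O)O",
    # lactones, quinones, misc natural products
    "CC1=CC2OC(=O)C(C)C2CC1",
    "CC1CCC2C(C)C(=O)OC3OC4(C)CCC1C23OO4",
    "O=C1C=Cc2ccccc2C1=O",
    "CC1=CC(=O)c2ccccc2C1=O",
    "Cc1cc2C(=O)c3cc(O)cc(O)c3C(=O)c2c(O)c1O",
    "Oc1ccc2c(c1)C(=O)c1cc(O)ccc1C2=O",
    "COC1=CC(=O)CC(C)C12Oc1c(Cl)c(OC)cc(OC)c1C2=O",
    "CC(=O)c1c(O)cc(O)cc1O",
    "CC(C)=CCc1c(O)cc(O)c2c1oc(-c1ccc(O)cc1)cc2=O",
    "O=C(/C=C/c1ccc(O)c(O)c1)OC1CC(O)(C(=O)O)CC(O)C1O",
    "COc1cc(C2c3cc4c(cc3C(O)C3COC(=O)C23)OCO4)cc(OC)c1O",
    "O=C1OCC2C1Cc1ccccc1C2c1ccc2c(c1)OCO2",
    "CC(=O)OCC(=O)C1(O)CCC2C3CCC4=CC(=O)CCC4(C)C3C(O)CC21C",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "CC(C)NCC(O)c1ccc(O)c(O)c1",
    "CC(C)NCC(O)COc1ccc2ccccc2c1",
    "CC(C)NCC(O)COc1ccccc1CC=C",
    "COCCc1ccc(OCC(O)CNC(C)C)cc1",
    "CC(C)C(=O)OCC(=O)C1(O)CCC2C3CCC4=CC(=O)C=CC4(C)C3C(O)CC21C",
    # small heterocycles and drugs
    "Clc1ccc(C(=O)NCCN2CCCC2)cc1",
    "O=C(NCCN1CCCC1)c1ccc(N)cc1",
    "CC(=O)Nc1nnc(S(N)(=O)=O)s1",
    "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",
    "NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl",
    "CCOC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]",
    "COC(=O)C1=C(C)NC(C)=C(C(=O)OCC)C1c1cccc([N+](=O)[O-])c1",
    "Cc1ncc([N+](=O)[O-])n1CCO",
    "Cc1ncc([N+](=O)[O-])n1CCOC(C)=O",
    "OCCn1ccnc1",
    "Clc1ccc2nc(NC3CC3)c(-c3ccncc3)nc2c1",
    "CC(C)Cc1nc2ccccc2n1Cc1ccc(-c2ccccc2C(=O)O)cc1",
    "CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nn[nH]n2)cc1",
    "O=C(O)c1ccc(-c2ccccc2)nc1",
    "Cc1ccc(S(=O)(=O)Nc2ccccn2)cc1",
    "Nc1ncnc2c1ncn2C1OC(CO)C(O)C1O",
    "Nc1nc2c(ncn2C2OC(CO)C(O)C2O)c(=O)[nH]1",
    "Cn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21",
    "CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCN(C)CC3)cc21",
    "Cc1onc(-c2ccccc2)c1C(=O)O",
    "Cc1oncc1C(=O)Nc1ccccc1",
    "CSc1ccc2c(c1)[nH]c1ccccc12",
    "Fc1ccc(C(=O)CCCN2CCC(O)(c3ccc(Cl)cc3)CC2)cc1",
    "COc1ccc(CCN2CCC(Nc3nc4ccccc4n3Cc3ccc(F)cc3)CC2)cc1",
    "O=C(Nc1ccc(Cl)cc1)c1cc(O)c2ccccc2n1",
    "Cc1cccc(C)c1NC(=O)C1CCCN1C",
    "COc1ccc(Cl)cc1C(=O)NCCc1ccc(S(=O)(=O)NC(=O)NC2CCCCC2)cc1",
    "O=S(=O)(Nc1ccccn1)c1ccc(N)cc1",
    "Nc1ccc(S(=O)(=O)Nc2ncccn2)cc1",
    "Nc1ccc(S(N)(=O)=O)cc1",
    "CN(C)c1ccc(/N=N/c2ccc(S(N)(=O)=O)cc2)cc1",
    "Cc1cc(C)c(NC(=O)CN2CCN(C)CC2)c(C)c1",
    "O=C(O)CN1C(=O)C(=O)Nc2ccccc21",
    "O=c1[nH]c2ccccc2n1C1CCN(CCCC(=O)c2ccc(F)cc2)CC1",
    "CC(C)(Oc1ccc(CCNC(=O)c2ccc(Cl)cc2)cc1)C(=O)O",
    "CC(C)(Oc1ccc(Cl)cc1)C(=O)OCC",
    "CCOC(=O)c1ncn2c1CN(C)C(=O)c1cc(F)ccc12",
    "Cn1c2ccc(Cl)cc2c2nc(C)nn2c1=O",
    "Oc1nc2ccccc2s1",
    "S=c1[nH]c2ccccc2[nH]1",
    "Cc1nnc2ccc(-c3ccccc3)nn12",
    "COc1ccc(-c2nnc3ccccn23)cc1",
    "O=C(Nc1ccccc1)Nc1ccccc1",
    "CN(C)C(=O)Nc1ccc(Cl)cc1",
    "CNC(=O)Oc1cccc2ccccc12",
    "CNC(=O)Oc1ccccc1OC(C)C",
    "COC(=O)Nc1nc2cc(C(=O)c3ccccc3)ccc2[nH]1",
    "COC(=O)Nc1nc2cc(Sc3ccccc3)ccc2[nH]1",
    "OCC(O)CO",
    "CC(O)C(O)c1ccc(O)c(O)c1",
    "OCC(O)C(O)C(O)C(O)CO",
    "OC1CCCCC1O",
    "OCC1OC(O)C(O)C(O)C1O",
    "CC(=O)NC1C(O)OC(CO)C(O)C1O",
    # fatty/organic acids & esters
    "CCCCCCCC/C=C\\CCCCCCCC(=O)O",
    "CCCCCCCCCCCCCCCC(=O)O",
    "CCCCC/C=C\\C/C=C\\CCCCCCCC(=O)O",
    "CC(=O)OCC(COC(C)=O)OC(C)=O",
    "CCCCCOC(=O)c1ccc(N)cc1",
    "CCOC(=O)/C=C/c1ccccc1",
    "COC(=O)c1ccc(O)cc1",
    "CCOC(=O)c1ccccc1O",
    # additional scaffolds for diversity
    "O=C1NC(=O)C2(CCCCC2)N1",
    "O=C1CCCN1c1ccccc1",
    "O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1",
    "Cc1ccc(-n2nc(C(C)(C)C)cc2NC(=O)Nc2ccc3ncsc3c2)cc1",
    "CC(C)n1c(/C=C/C(O)CC(O)CC(=O)O)c(-c2ccc(F)cc2)c2ccccc21",
    "Cc1c(C(=O)Nc2ccccc2)noc1-c1ccccc1",
    "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1",
    "Cc1cn(C2CC(O)C(CO)O2)c(=O)[nH]c1=O",
    "Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1",
    "OC1CC(n2cnc3c2ncnc3N)CC1CO",
    "CC1CN(c2cc3c(cc2F)c(=O)c(C(=O)O)cn3C2CC2)CCN1",
    "CC(C)(C)c1cc(C(C)(C)C)c(O)c(O)c1",
    "CC(C)(C)c1cc(/C=C/C(=O)O)cc(C(C)(C)C)c1O",
    "Oc1ccc(Cc2ccc(O)cc2)cc1",
    "Oc1ccc(-c2ccc(O)cc2)cc1",
    "Oc1ccc(S(=O)(=O)c2ccc(O)cc2)cc1",
    "Oc1ccc(C(=O)c2ccc(O)cc2)cc1",
    "COc1ccc(C(=O)/C=C/c2ccc(O)cc2)cc1O",
    "Oc1ccc(/C=C/C(=O)c2ccc(O)cc2O)cc1",
    "COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O",
)
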