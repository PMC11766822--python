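compound_id,name,smiles
DEX,Dexamethasone,CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO
HC,Hydrocortisone (HC),OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
PROG,Progesterone,CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
PRED,Prednisolone,OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)C=CC12C
E1,Estrone,O=C1CCC2C1(C)CCC3C2CCc2cc(O)ccc23
ALDO,Aldosterone,OCC(=O)C1CCC2C1(C=O)CC(O)C1C2CCC2=CC(=O)CCC12C
CORT,Corticosterone,OCC(=O)C1CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
PREG,Pregnenolone,CC(=O)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C
OHP17,17-α-Hydroxyprogesterone,CC(=O)C1(O)CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
OHPREG17,17-α-Hydroxypregnenolone,CC(=O)C1(O)CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C
DOC,Deoxycorticosterone,OCC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
TST,Testosterone,OC1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
CORTEX,Cortexolone,OCC(=O)C1(O)CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
E2,Estradiol,OC1CCC2C1(C)CCC3C2CCc2cc(O)ccc23
E3,Estriol,OC1C(O)CC2C1(C)CCC3C2CCc2cc(O)ccc23
CORTN,Cortisone,OCC(=O)C1(O)CCC2C1(C)CC(=O)C1C2CCC2=CC(=O)CCC12C
HC-SUCAM,HC succinamate,NC(=O)CCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-DMSUCAM,"HC N,N-dimethylsuccinamate",CN(C)C(=O)CCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-MESUC,HC methylsuccinate,COC(=O)CCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-HEMISUC,HC hemisuccinate,OC(=O)CCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-PIM,HC pimelate,OC(=O)CCCCCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-PIMAM,HC pimelamate,NC(=O)CCCCCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-6OHHEX,HC 6-hydroxyhexanoate,OCCCCCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-PROP,HC propionate,CCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-MEPIM,HC methylpimelate,COC(=O)CCCCCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-HEX,HC hexanoate,CCCCCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
HC-OCT,HC octanoate,CCCCCCCC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
E2-BZ,Estradiol benzoate,OC1CCC2C1(C)CCC3C2CCc2cc(OC(=O)c4ccccc4)ccc23
HC-AC,HC acetate,CC(=O)OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C
DOCA,Deoxycortisone acetate,CC(=O)OCC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
CORTN-AC,Cortisone acetate,CC(=O)OCC(=O)C1(O)CCC2C1(C)CC(=O)C1C2CCC2=CC(=O)CCC12C
TST-PROP,Testosterone propionate,CCC(=O)OC1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
MT,Methyltestosterone,OC1(C)CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
TST-EN,Testosterone enanthate,CCCCCCC(=O)OC1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
SPIRO,Spironolactone,CC(=O)SC1CC2=CC(=O)CCC2(C)C2CCC3(C)C(C12)CCC31CCC(=O)O1
EPL,Eplerenone,COC(=O)C1CC2=CC(=O)CCC2(C)C34OC4CC5(C)C6(CCC(=O)O6)CCC5C13
TIB,Tibolone,C#CC1(O)CCC2C1(C)CCC1C2CC(C)C2=C1CCC(=O)C2
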