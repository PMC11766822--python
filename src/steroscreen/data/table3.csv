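compound_id,name,k_gst,k_nat2
DEX,Dexamethasone,-9.1,-9.0
HC,Hydrocortisone (HC),-9.3,-8.6
PROG,Progesterone,-9.6,-9.6
PRED,Prednisolone,-9.2,-8.5
E1,Estrone,-9.1,-10.6
ALDO,Aldosterone,-9.4,-8.5
CORT,Corticosterone,-9.4,-8.7
PREG,Pregnenolone,-8.4,-9.0
OHP17,17-α-Hydroxyprogesterone,-9.2,-9.5
OHPREG17,17-α-Hydroxypregnenolone,-8.6,-8.8
DOC,Deoxycorticosterone,-9.4,-8.7
TST,Testosterone,-8.8,-9.6
CORTEX,Cortexolone,-9.3,-8.9
E2,Estradiol,-8.9,-10.3
E3,Estriol,-9.0,-10.2
CORTN,Cortisone,-9.1,-9.0
HC-SUCAM,HC succinamate,-9.1,-9.9
HC-DMSUCAM,"HC N,N-dimethylsuccinamate",-9.4,-9.8
HC-MESUC,HC methylsuccinate,-8.4,-9.7
HC-HEMISUC,HC hemisuccinate,-8.6,-9.8
HC-PIM,HC pimelate,-8.5,-10.0
HC-PIMAM,HC pimelamate,-9.0,-9.9
HC-6OHHEX,HC 6-hydroxyhexanoate,-7.9,-10.0
HC-PROP,HC propionate,-8.8,-9.7
HC-MEPIM,HC methylpimelate,-8.7,-10.0
HC-HEX,HC hexanoate,-8.0,-9.9
HC-OCT,HC octanoate,-8.3,-9.9
E2-BZ,Estradiol benzoate,-10.0,-11.3
HC-AC,HC acetate,-9.3,-9.7
DOCA,Deoxycortisone acetate,-9.0,-9.9
CORTN-AC,Cortisone acetate,-9.2,-9.9
TST-PROP,Testosterone propionate,-8.6,-9.5
MT,Methyltestosterone,-8.8,-9.2
TST-EN,Testosterone enanthate,-8.0,-10.1
SPIRO,Spironolactone,-9.3,-7.6
EPL,Eplerenone,-10.6,-7.1
TIB,Tibolone,-8.4,-8.5
REF,Reference ligands (glutathione / CoA),-5.4,-7.4
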