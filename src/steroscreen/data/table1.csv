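compound_id,name,log_koc,mobility,log_bcf,bioaccumulative,log_bb,log_ps,log_kpuubr,bbb,pgp_substrate,hia_pct,log_kp_skin,log_fm,placenta_noncrossing,lipinski_violations
DEX,Dexamethasone,2.02,MM/SM,0.95,0,-0.70,-3.42,-1.32,BBB-,Yes,81.31,-3.97,-0.33,0,0
HC,Hydrocortisone (HC),1.72,VM/M,0.73,0,-0.48,-2.59,-1.27,BBB-,Yes,75.27,-4.35,-0.43,0,0
PROG,Progesterone,3.73,MM/SM,2.22,0,0.09,-1.93,-0.01,BBB+,No,99.27,-2.22,-0.46,0,0
PRED,Prednisolone,1.72,VM/M,0.74,0,-0.50,-3.36,-1.36,BBB-,Yes,73.69,-4.47,-0.40,0,0
E1,Estrone,3.70,MM/SM,1.73,0,-0.04,-1.74,-0.14,BBB+,Yes,96.42,-2.62,-0.41,0,0
ALDO,Aldosterone,0.77,VM/M,0.50,0,-0.16,-2.55,-1.55,BBB-,Yes,79.71,-4.45,-0.42,0,0
CORT,Corticosterone,1.71,VM/M,0.95,0,0.07,-2.22,-0.85,BBB-,Yes,96.95,-4.29,-0.48,0,0
PREG,Pregnenolone,3.43,MM/SM,2.45,0,0.09,-2.37,-0.13,BBB+,No,95.63,-2.77,-0.52,0,0
OHP17,17-α-Hydroxyprogesterone,2.77,MM/SM,1.76,0,0.18,-1.75,-0.33,BBB+,Yes,96.03,-3.40,-0.47,0,0
OHPREG17,17-α-Hydroxypregnenolone,2.55,MM/SM,2.17,0,-0.09,-1.70,-0.64,BBB-,Yes,95.73,-3.17,-0.61,1,0
DOC,Deoxycorticosterone,2.73,MM/SM,1.57,0,-0.06,-1.90,-0.46,BBB+,Yes,98.19,-3.41,-0.47,0,0
TST,Testosterone,2.94,MM/SM,1.86,0,0.16,-2.08,-0.04,BBB+,No,96.54,-3.06,-0.45,0,0
CORTEX,Cortexolone,2.02,MM/SM,1.70,0,0.17,-2.26,-0.69,BBB-,Yes,96.58,-4.18,-0.49,0,0
E2,Estradiol,3.54,MM/SM,2.31,0,-0.07,-1.33,-0.14,BBB+,Yes,93.90,-2.97,-0.43,0,0
E3,Estriol,2.35,MM/SM,1.28,0,-0.22,-2.10,-0.57,BBB-,Yes,94.47,-3.29,-0.43,0,0
CORTN,Cortisone,1.68,VM/M,0.64,0,-0.01,-2.50,-1.27,BBB-,Yes,88.79,-4.71,-0.41,0,0
HC-SUCAM,HC succinamate,1.32,VM/M,0.61,0,-0.89,-3.34,-2.29,BBB-,Yes,71.11,-3.60,-0.46,0,0
HC-DMSUCAM,"HC N,N-dimethylsuccinamate",1.49,VM/M,1.01,0,-0.89,-3.16,-1.82,BBB-,Yes,74.44,-3.76,-0.45,0,0
HC-MESUC,HC methylsuccinate,1.62,VM/M,1.38,0,-0.49,-2.82,-1.13,BBB-,Yes,77.28,-3.45,-0.53,1,0
HC-HEMISUC,HC hemisuccinate,0.91,VM/M,0.50,0,-1.02,-3.29,-2.31,BBB-,Yes,50.08,-2.74,-0.48,0,0
HC-PIM,HC pimelate,1.53,VM/M,0.50,0,-1.42,-2.86,-2.15,BBB-,Yes,53.29,-2.74,-0.42,0,1
HC-PIMAM,HC pimelamate,1.95,VM/M,1.18,0,-1.03,-3.17,-2.01,BBB-,Yes,72.20,-3.41,-0.41,0,1
HC-6OHHEX,HC 6-hydroxyhexanoate,2.38,MM/SM,1.51,0,-1.02,-3.12,-1.19,BBB-,Yes,77.50,-3.71,-0.51,0,0
HC-PROP,HC propionate,1.86,VM/M,1.51,0,-0.42,-2.79,-0.77,BBB-,Yes,83.46,-4.28,-0.43,0,0
HC-MEPIM,HC methylpimelate,2.31,MM/SM,2.11,0,-0.52,-2.99,-1.27,BBB-,Yes,74.62,-3.27,-0.48,0,1
HC-HEX,HC hexanoate,2.71,MM/SM,2.62,0,-0.48,-2.73,-0.92,BBB-,Yes,85.63,-3.83,-0.57,1,0
HC-OCT,HC octanoate,3.25,MM/SM,3.29,1,-0.53,-2.70,-1.30,BBB-,Yes,87.03,-3.47,-0.63,1,0
E2-BZ,Estradiol benzoate,4.26,HM/IM,3.28,1,-0.10,-1.31,-0.08,BBB+,No,97.41,-2.67,-0.49,0,1
HC-AC,HC acetate,1.29,VM/M,0.50,0,-0.87,-3.22,-1.94,BBB-,Yes,77.35,-3.36,-0.37,0,0
DOCA,Deoxycortisone acetate,3.32,MM/SM,1.70,0,-0.06,-1.70,-0.76,BBB-,No,100.00,-2.57,-0.49,0,0
CORTN-AC,Cortisone acetate,2.39,MM/SM,1.05,0,-0.39,-2.66,-1.03,BBB-,Yes,86.28,-4.27,-0.41,0,0
TST-PROP,Testosterone propionate,4.03,HM/IM,2.81,0,0.26,-2.38,0.19,BBB+,No,97.44,-2.93,-0.49,0,0
MT,Methyltestosterone,3.04,MM/SM,1.88,0,0.21,-2.41,0.04,BBB+,No,95.58,-2.95,-0.55,1,0
TST-EN,Testosterone enanthate,5.09,HM/IM,4.11,1,0.20,-2.08,0.13,BBB+,No,95.00,-2.78,-0.55,1,1
SPIRO,Spironolactone,2.89,MM/SM,1.16,0,-0.10,-1.56,-0.54,BBB-,No,97.92,-3.35,-0.51,0,0
EPL,Eplerenone,2.58,MM/SM,0.69,0,-0.47,-2.95,-0.97,BBB-,No,100.00,-3.23,-0.46,0,0
TIB,Tibolone,3.36,MM/SM,2.26,0,0.15,-2.46,0.04,BBB+,Yes,96.26,-3.11,-0.51,0,0
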