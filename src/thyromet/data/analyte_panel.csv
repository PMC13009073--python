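analyte,parent,loq_ng_ml,molar_mass_ug_per_umol,family
Methylparaben,Methylparaben,0.50,,paraben
Ethylparaben,Ethylparaben,0.10,,paraben
Propylparaben,Propylparaben,0.50,,paraben
Butylparaben,Butylparaben,0.01,,paraben
MEHHP,DEHP,0.05,294,phthalate_metabolite
MEHP,DEHP,0.20,278,phthalate_metabolite
MEOHP,DEHP,0.10,292,phthalate_metabolite
MECPP,DEHP,0.05,308,phthalate_metabolite
MiBP,DiBP,0.05,222,phthalate_metabolite
MMP,DMP,0.20,,phthalate_metabolite
MBzP,BBzP,0.05,256,phthalate_metabolite
MCPP,DnBP,0.05,,phthalate_metabolite
MEP,DEP,0.10,194,phthalate_metabolite
MBP,DnBP,0.05,222,phthalate_metabolite
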