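name,chem_class,units,lod,pct_above_lod,gm,gsd,included,nhanes_median
MBP,PHTHALATE_BPA,ug/g creatinine,0.60,1.00,27.2,1.9,True,24
MIBP,PHTHALATE_BPA,ug/g creatinine,0.30,0.99,5.9,1.9,True,4.0
MEP,PHTHALATE_BPA,ug/g creatinine,0.53,1.00,152,3.0,True,120
MBZP,PHTHALATE_BPA,ug/g creatinine,0.22,0.98,9.8,2.4,True,10
MCPP,PHTHALATE_BPA,ug/g creatinine,0.20,0.99,2.4,1.9,True,2.9
MEHP,PHTHALATE_BPA,ug/g creatinine,1.20,0.98,5.9,2.8,True,2.2
MECPP,PHTHALATE_BPA,ug/g creatinine,0.60,1.00,41.3,2.5,True,31
MEHHP,PHTHALATE_BPA,ug/g creatinine,0.70,1.00,28.7,2.6,True,19
MEOHP,PHTHALATE_BPA,ug/g creatinine,0.70,1.00,22.3,2.5,True,
BPA,PHTHALATE_BPA,ug/g creatinine,0.4,0.96,2.1,1.9,True,2.7
PCB-28,PCB,ng/g lipid,0.79,0.82,0.7,3.1,False,5.0
PCB-44,PCB,ng/g lipid,0.53,0.92,0.07,1.8,True,
PCB-49,PCB,ng/g lipid,0.53,1.00,0.06,1.8,True,
PCB-52,PCB,ng/g lipid,0.53,0.91,0.1,3.1,True,
PCB-66,PCB,ng/g lipid,0.53,0.75,0.4,3.7,False,1.4
PCB-74,PCB,ng/g lipid,0.63,0.99,2.8,1.8,True,5.4
PCB-87,PCB,ng/g lipid,0.53,1.00,0.09,2.9,True,
PCB-99,PCB,ng/g lipid,0.53,0.99,2.7,2.1,True,3.9
PCB-101,PCB,ng/g lipid,0.53,0.32,0.1,2.1,False,1.6
PCB-105,PCB,ng/g lipid,0.53,0.93,1,2.8,True,1.2
PCB-110,PCB,ng/g lipid,0.53,0.99,0.09,3,True,
PCB-118,PCB,ng/g lipid,0.78,0.99,5,1.9,True,5.0
PCB-128,PCB,ng/g lipid,0.53,0.97,0.07,2.5,True,
PCB-146,PCB,ng/g lipid,0.53,0.93,1,2.9,True,2.3
PCB-149,PCB,ng/g lipid,0.53,0.97,0.08,2.5,True,
PCB-151,PCB,ng/g lipid,0.53,0.97,0.07,2.2,True,
PCB-153,PCB,ng/g lipid,0.81,1.00,11.4,1.9,True,22
PCB-156,PCB,ng/g lipid,0.53,0.96,1.6,2.4,True,3.4
PCB-157,PCB,ng/g lipid,0.53,0.51,0.2,3.7,False,0.9
PCB-167,PCB,ng/g lipid,0.53,0.59,0.2,3.9,False,0.9
PCB-170,PCB,ng/g lipid,0.61,1.00,2.9,2.2,True,6.3
PCB-172,PCB,ng/g lipid,0.53,0.34,0.1,3.5,False,0.9
PCB-177,PCB,ng/g lipid,0.53,0.61,0.2,4.1,False,1.3
PCB-178,PCB,ng/g lipid,0.53,0.52,0.2,4,False,1.2
PCB-180,PCB,ng/g lipid,0.78,1.00,6.7,2.1,True,
PCB-183,PCB,ng/g lipid,0.53,0.87,0.7,3.3,True,1.7
PCB-187,PCB,ng/g lipid,0.53,0.98,2,2.4,True,4.6
PCB-189,PCB,ng/g lipid,0.53,0.97,0.07,2.1,True,
PCB-194,PCB,ng/g lipid,0.53,0.92,1.3,2.7,True,4.0
PCB-195,PCB,ng/g lipid,0.53,0.39,0.1,3.5,False,0.6
PCB-199,PCB,ng/g lipid,0.53,0.93,1.2,2.9,True,3.7
PCB-206,PCB,ng/g lipid,0.53,0.81,0.9,3.5,True,2.3
PCB-209,PCB,ng/g lipid,0.53,0.35,0.1,3.2,False,1.2
PCB-38/158,PCB,ng/g lipid,0.78,0.99,8,2.1,False,16
PCB-196/203,PCB,ng/g lipid,0.53,0.96,1.5,2.4,False,3.3
PFOA,PFAS,ug/L serum,6.05,1.00,5.6,1.7,True,3.6
PFOS,PFAS,ug/L serum,14.2,1.00,13.6,1.5,True,18
PFNA,PFAS,ug/L serum,0.96,1.00,1,1.4,True,0.9
PFHXS,PFAS,ug/L serum,1.96,1.00,1.6,2,True,1.6
PFDEA,PFAS,ug/L serum,0.21,0.30,0.2,1.6,True,
BB-153,PBDE,ng/g lipid,0.53,0.85,0.9,4.1,False,
PBDE-17,PBDE,ng/g lipid,0.53,0.96,0.07,2.2,True,
PBDE-28,PBDE,ng/g lipid,0.53,0.81,0.7,4.1,True,1.0
PBDE-47,PBDE,ng/g lipid,0.86,1.00,19.1,2.7,True,19
PBDE-66,PBDE,ng/g lipid,0.53,0.92,0.06,2,True,
PBDE-85,PBDE,ng/g lipid,0.53,0.49,0.2,4.8,True,
PBDE-99,PBDE,ng/g lipid,0.65,1.00,4.4,2.9,True,
PBDE-100,PBDE,ng/g lipid,0.53,0.99,3.7,3,True,3.2
PBDE-153,PBDE,ng/g lipid,0.53,0.99,5.2,3.3,True,4.0
PBDE-154,PBDE,ng/g lipid,0.53,0.42,0.2,4.7,False,0.8
PBDE-183,PBDE,ng/g lipid,0.53,0.08,0.1,3.3,True,
b-HCH,OCP,ng/g lipid,2.63,0.27,0.5,3.5,True,
HCB,OCP,ng/g lipid,3.92,0.94,6.6,1.9,True,16
pp-DDT,OCP,ng/g lipid,2.63,0.52,1.1,3.7,True,
pp-DDE,OCP,ng/g lipid,2.63,1.00,74,1.8,True,206
Oxychlordane,OCP,ng/g lipid,2.63,0.90,4.4,2.5,True,11
trans-Nonachlor,OCP,ng/g lipid,2.63,0.97,7.5,2.1,True,15
DEP,OPP,ug/L serum,0.56,0.08,0.08,5.4,True,
DMP,OPP,ug/L serum,0.62,0.27,0.4,4.2,True,
Pb,METAL,ug/dL,0.25,0.96,0.7,1.4,True,
Hg,METAL,ug/L serum,0.2,0.79,0.6,2.3,True,
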