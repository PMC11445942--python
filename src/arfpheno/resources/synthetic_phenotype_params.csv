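# Synthetic per-phenotype feature parameter dictionary (median / Q1 / Q3 on original units).
# Rows for the published derivation-cohort summary variables carry the printed medians and IQRs;
# every other row is a SYNTHETIC stand-in with clinically plausible values chosen to be consistent
# with each phenotype's organ-injury pattern (A renal/cardiac, B hypoxemic, C mild, D hepatic/coag).
# lo/hi are physiologic plausibility bounds, also used for outlier screening.
feature,unit,kind,family,lo,hi,missingness,block,a_med,a_q1,a_q3,b_med,b_q1,b_q3,c_med,c_q1,c_q3,d_med,d_q1,d_q3
pf_ratio,mmHg,lab,truncnorm,20,700,0.30,respiratory,302.3,226.7,406.4,123.3,90.0,185.0,240.0,185.0,317.7,266.5,196.5,346.7
sf_ratio,ratio,vital,truncnorm,30,500,0.15,respiratory,250.0,240.0,326.7,120.8,97.5,154.8,248.8,232.5,320.4,247.5,220.0,325.0
fio2,fraction,vital,truncnorm,0.21,1.0,0.10,respiratory,0.4,0.3,0.4,0.8,0.6,1.0,0.4,0.3,0.4,0.4,0.3,0.4
pao2,mmHg,lab,truncnorm,30,500,0.30,respiratory,107.0,86.0,146.1,81.0,67.0,102.0,92.0,77.7,116.1,99.2,79.6,125.9
paco2,mmHg,lab,truncnorm,10,150,0.30,respiratory,37.0,32.0,43.0,38.5,33.0,45.0,39.0,34.0,46.9,33.0,29.0,38.0
map,mmHg,vital,truncnorm,30,200,0.02,cardio,79.0,73.0,87.5,85.0,77.0,94.0,87.0,80.0,95.0,77.0,72.0,84.0
creatinine,mg/dL,lab,lognormal,0.1,40,0.10,renal,3.5,1.9,5.7,1.3,0.8,2.1,1.1,0.8,1.5,1.4,0.9,2.5
bilirubin_total,mg/dL,lab,lognormal,0.05,60,0.15,hepatic,0.8,0.5,1.4,0.6,0.4,1.0,0.6,0.4,1.1,1.2,0.6,4.1
albumin,g/dL,lab,truncnorm,0.5,6,0.15,hepatic,2.9,2.5,3.3,3.1,2.7,3.5,3.4,3.0,3.8,2.6,2.2,2.9
lactate,mmol/L,lab,lognormal,0.2,30,0.20,cardio,1.5,1.2,2.1,1.6,1.2,2.3,1.4,1.1,2.0,2.3,1.4,4.7
d_dimer,ng/mL,lab,lognormal,50,100000,0.55,coag,3177.0,1427.0,6981.5,1573.0,979.0,4622.0,1686.5,897.8,5183.0,9828.0,3187.0,27545.0
platelets,1e3/uL,lab,truncnorm,1,1500,0.10,coag,175.0,112.0,245.0,209.0,143.0,286.0,213.0,149.0,291.0,118.0,53.0,202.8
hemoglobin,g/dL,lab,truncnorm,2,25,0.10,heme,8.8,7.8,10.3,11.0,9.0,12.8,11.5,9.7,13.4,8.6,7.7,10.2
bnp,pg/mL,lab,lognormal,5,70000,0.50,cardio,750.5,251.2,1775.5,142.8,60.0,441.8,279.0,82.0,664.0,396.0,147.5,966.0
bun,mg/dL,lab,lognormal,1,300,0.10,renal,56.0,34.0,80.2,28.0,17.5,46.0,22.0,14.0,33.0,28.0,18.0,42.0
gcs_total,points,vital,truncnorm,3,15,0.10,neuro,14.0,12.0,15.0,15.0,11.2,15.0,14.0,12.0,15.0,14.0,11.0,15.0
heart_rate,bpm,vital,truncnorm,30,250,0.02,cardio,96,84,110,110,96,124,88,78,100,104,90,118
resp_rate,breaths/min,vital,truncnorm,4,70,0.02,respiratory,21,17,26,32,26,38,19,16,23,23,18,28
temperature,degC,vital,truncnorm,30,43,0.05,inflam,37.0,36.5,37.6,37.4,36.8,38.2,37.0,36.6,37.5,37.2,36.6,37.9
spo2,%,vital,truncnorm,40,100,0.02,respiratory,97,95,99,88,84,92,97,95,99,96,94,98
sbp,mmHg,vital,truncnorm,40,300,0.02,cardio,112,100,128,118,105,134,122,110,138,106,96,120
dbp,mmHg,vital,truncnorm,20,200,0.02,cardio,60,53,69,64,56,73,66,58,75,58,51,66
sodium,mmol/L,lab,truncnorm,100,180,0.08,metabolic,139,136,142,139,135,143,138,135,141,133,130,136
potassium,mmol/L,lab,truncnorm,1.5,10,0.08,renal,5.2,4.7,5.8,4.1,3.8,4.5,3.9,3.6,4.2,4.4,4.0,4.9
chloride,mmol/L,lab,truncnorm,70,140,0.08,metabolic,102,97,107,103,99,108,103,99,107,101,96,106
bicarbonate,mmol/L,lab,truncnorm,5,60,0.08,metabolic,16,13.5,19,23,20,25.5,24,21.5,26.5,17,14,20
anion_gap,mmol/L,lab,truncnorm,2,50,0.10,metabolic,18,15,22,13,11,15.5,11,9.5,13,20,16,24.5
wbc,1e3/uL,lab,lognormal,0.1,200,0.08,heme,12.5,8.5,18,11.8,8,16.5,10.9,7.8,15,13.6,8.6,20
neutrophils_pct,%,lab,truncnorm,1,100,0.20,heme,82,74,88,84,77,89,81,73,87,83,75,89
lymphocytes_pct,%,lab,lognormal,0.2,80,0.20,heme,8,5,13,7,4,12,9,6,14,7,4,12
glucose,mg/dL,lab,lognormal,20,1200,0.08,metabolic,145,115,190,142,112,200,131,105,175,110,88,140
ast,U/L,lab,lognormal,5,8000,0.15,hepatic,52,32,85,44,28,70,34,23,52,350,200,640
alt,U/L,lab,lognormal,5,6000,0.15,hepatic,36,23,58,31,20,50,26,17,40,185,105,330
alk_phos,U/L,lab,lognormal,10,2000,0.15,hepatic,98,72,134,86,63,118,80,59,108,235,150,360
inr,ratio,lab,lognormal,0.5,15,0.15,coag,1.3,1.15,1.5,1.2,1.05,1.4,1.1,1.0,1.25,2.3,1.8,3.0
ptt,s,lab,lognormal,15,200,0.20,coag,33,28,40,31,27,36,29,26,33,55,42,73
ph,pH,lab,truncnorm,6.6,7.8,0.30,metabolic,7.31,7.25,7.37,7.35,7.28,7.41,7.39,7.34,7.43,7.22,7.12,7.31
base_excess,mmol/L,lab,truncnorm,-30,30,0.30,metabolic,-6,-9,-3,-2,-4.5,0.5,0,-2.5,2.5,-10,-14,-6.5
troponin,ng/mL,lab,lognormal,0.01,100,0.35,cardio,0.85,0.35,2.0,0.08,0.04,0.18,0.04,0.02,0.09,0.12,0.05,0.28
ck,U/L,lab,lognormal,10,50000,0.50,inflam,520,240,1100,150,80,290,120,65,220,150,80,290
magnesium,mg/dL,lab,truncnorm,0.5,10,0.10,metabolic,2.1,1.8,2.4,2.0,1.8,2.3,2.0,1.8,2.3,2.1,1.8,2.4
phosphate,mg/dL,lab,lognormal,0.3,20,0.15,renal,6.2,5.0,7.7,3.6,3.0,4.3,3.3,2.8,3.9,3.8,3.0,4.7
calcium,mg/dL,lab,truncnorm,4,18,0.10,metabolic,8.3,7.8,8.9,8.5,8.0,9.0,8.6,8.1,9.1,8.1,7.6,8.7
hematocrit,%,lab,truncnorm,6,75,0.10,heme,27,24,31.5,33.5,27.5,38.5,34.8,29.5,40.5,26.5,23.5,31
rdw,%,lab,truncnorm,10,35,0.10,heme,15.2,14.0,16.6,15.0,13.8,16.4,14.9,13.7,16.3,17.8,16.2,19.6
mcv,fL,lab,truncnorm,50,140,0.10,heme,88,84,93,90,85,96,90,86,96,98,92,104
urine_output_rate,mL/h,vital,lognormal,0.5,400,0.25,renal,12,6,22,55,34,85,75,50,108,50,30,78
ferritin,ng/mL,lab,lognormal,5,100000,0.50,inflam,520,260,1050,560,280,1150,320,165,630,2600,1500,4400
crp,mg/L,lab,lognormal,0.1,600,0.55,inflam,80,35,150,135,60,250,75,33,140,200,95,370
fibrinogen,mg/dL,lab,truncnorm,30,1500,0.90,coag,420,300,560,440,320,580,450,330,590,300,190,430
procalcitonin,ng/mL,lab,lognormal,0.02,500,0.90,inflam,1.8,0.5,7,1.2,0.4,4.5,0.8,0.3,2.8,3.5,0.9,14
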