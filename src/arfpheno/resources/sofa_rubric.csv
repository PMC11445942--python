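component,variable,op,threshold,score,requires_ventilation
respiration,pf_ratio,lt,400,1,0
respiration,pf_ratio,lt,300,2,0
respiration,pf_ratio,lt,200,3,1
respiration,pf_ratio,lt,100,4,1
coagulation,platelets,lt,150,1,0
coagulation,platelets,lt,100,2,0
coagulation,platelets,lt,50,3,0
coagulation,platelets,lt,20,4,0
hepatic,bilirubin_total,ge,1.2,1,0
hepatic,bilirubin_total,ge,2.0,2,0
hepatic,bilirubin_total,ge,6.0,3,0
hepatic,bilirubin_total,ge,12.0,4,0
cardiovascular,map,lt,70,1,0
cardiovascular,dobutamine,gt,0,2,0
cardiovascular,dopamine,gt,0,2,0
cardiovascular,dopamine,gt,5,3,0
cardiovascular,norepinephrine,gt,0,3,0
cardiovascular,epinephrine,gt,0,3,0
cardiovascular,dopamine,gt,15,4,0
cardiovascular,norepinephrine,gt,0.1,4,0
cardiovascular,epinephrine,gt,0.1,4,0
cns,gcs_total,le,14,1,0
cns,gcs_total,le,12,2,0
cns,gcs_total,le,9,3,0
cns,gcs_total,lt,6,4,0
renal,creatinine,ge,1.2,1,0
renal,creatinine,ge,2.0,2,0
renal,creatinine,ge,3.5,3,0
renal,creatinine,ge,5.0,4,0
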