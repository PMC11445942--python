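category,weight,supersedes,prefixes
myocardial_infarction,1,,410;412
congestive_heart_failure,1,,428
peripheral_vascular,1,,441;443.9;785.4;V43.4
cerebrovascular,1,,430;431;432;433;434;435;436;437;438
dementia,1,,290
chronic_pulmonary,1,,490;491;492;493;494;495;496;500;501;502;503;504;505;506.4
rheumatic,1,,710.0;710.1;710.4;714.0;714.1;714.2;714.81;725
peptic_ulcer,1,,531;532;533;534
mild_liver,1,,571.2;571.4;571.5;571.6
diabetes,1,,250.0;250.1;250.2;250.3;250.7
diabetes_complicated,2,diabetes,250.4;250.5;250.6
hemiplegia,2,,342;344.1
renal_disease,2,,582;583;585;586;588
malignancy,2,,140;141;142;143;144;145;146;147;148;149;150;151;152;153;154;155;156;157;158;159;160;161;162;163;164;165;170;171;172;174;175;176;179;180;181;182;183;184;185;186;187;188;189;190;191;192;193;194;195;200;201;202;203;204;205;206;207;208
moderate_severe_liver,3,mild_liver,456.0;456.1;456.2;572.2;572.3;572.4;572.8
metastatic,6,malignancy,196;197;198;199.0;199.1
aids,6,,042;043;044
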