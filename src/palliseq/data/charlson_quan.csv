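condition,weight,codes
myocardial_infarction,1,I21;I22;I252
congestive_heart_failure,1,I099;I110;I130;I132;I255;I420;I425-I429;I43;I50;P290
peripheral_vascular,1,I70;I71;I731;I738;I739;I771;I790;I792;K551;K558;K559;Z958;Z959
cerebrovascular,1,G45;G46;H340;I60-I69
dementia,1,F00-F03;F051;G30;G311
chronic_pulmonary,1,I278;I279;J40-J47;J60-J67;J684;J701;J703
rheumatic,1,M05;M06;M315;M32-M34;M351;M353;M360
peptic_ulcer,1,K25-K28
mild_liver,1,B18;K700-K703;K709;K713-K715;K717;K73;K74;K760;K762-K764;K768;K769;Z944
diabetes_uncomplicated,1,E100;E101;E106;E108;E109;E110;E111;E116;E118;E119;E120;E121;E126;E128;E129;E130;E131;E136;E138;E139;E140;E141;E146;E148;E149
diabetes_complicated,2,E102-E105;E107;E112-E115;E117;E122-E125;E127;E132-E135;E137;E142-E145;E147
hemiplegia,2,G041;G114;G801;G802;G81;G82;G830-G834;G839
renal,2,I120;I131;N032-N037;N052-N057;N18;N19;N250;Z490-Z492;Z940;Z992
malignancy,2,C00-C26;C30-C34;C37-C41;C43;C45-C58;C60-C76;C81-C85;C88;C90-C97
severe_liver,3,I850;I859;I864;I982;K704;K711;K721;K729;K765;K766;K767
metastatic_tumor,6,C77-C80
hiv,6,B20-B22;B24
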