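subject,estimator,condition,value,ci_lo,ci_hi
AN,nonparametric,intermodal,143,141,145
MS,nonparametric,intermodal,123,121,125
KS,nonparametric,intermodal,111,109,113
WF,nonparametric,intermodal,62,60,63
PK,nonparametric,intermodal,59,57,60
AN,nonparametric,intramodal,14,13,15
MS,nonparametric,intramodal,23,22,24
KS,nonparametric,intramodal,37,36,38
WF,nonparametric,intramodal,21,20,22
PK,nonparametric,intramodal,28,27,29
AN,nonparametric,difference,129,127,131
MS,nonparametric,difference,100,98,103
KS,nonparametric,difference,74,73,77
WF,nonparametric,difference,41,39,42
PK,nonparametric,difference,31,29,32
AN,parametric_c_su,intermodal,149,147,151
MS,parametric_c_su,intermodal,131,128,133
KS,parametric_c_su,intermodal,115,112,117
WF,parametric_c_su,intermodal,62,61,64
PK,parametric_c_su,intermodal,59,57,60
AN,parametric_c_su,intramodal,14,13,15
MS,parametric_c_su,intramodal,22,21,23
KS,parametric_c_su,intramodal,36,35,37
WF,parametric_c_su,intramodal,21,20,22
PK,parametric_c_su,intramodal,28,27,29
AN,parametric_c_su,difference,135,133,137
MS,parametric_c_su,difference,109,106,111
KS,parametric_c_su,difference,79,76,81
WF,parametric_c_su,difference,41,40,43
PK,parametric_c_su,difference,31,29,32
AN,parametric_c_o,intermodal,164,161,166
MS,parametric_c_o,intermodal,146,143,149
KS,parametric_c_o,intermodal,134,131,136
WF,parametric_c_o,intermodal,68,66,71
PK,parametric_c_o,intermodal,72,70,74
AN,parametric_c_o,intramodal,16,14,17
MS,parametric_c_o,intramodal,24,23,25
KS,parametric_c_o,intramodal,38,37,39
WF,parametric_c_o,intramodal,27,26,28
PK,parametric_c_o,intramodal,29,28,30
AN,parametric_c_o,difference,148,145,151
MS,parametric_c_o,difference,122,118,124
KS,parametric_c_o,difference,96,93,99
WF,parametric_c_o,difference,41,38,44
PK,parametric_c_o,difference,43,41,45
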