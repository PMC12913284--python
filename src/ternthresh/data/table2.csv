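subject,estimator,condition,value,ci_lo,ci_hi
ER,nonparametric,weak,167,160,172
LD,nonparametric,weak,209,203,213
VS,nonparametric,weak,69,65,73
CL,nonparametric,weak,180,175,185
ML,nonparametric,weak,104,97,110
MM,nonparametric,weak,302,298,306
FL,nonparametric,weak,218,211,226
RZ,nonparametric,weak,123,118,127
LF,nonparametric,weak,296,292,303
SE,nonparametric,weak,155,151,161
ER,nonparametric,strong,133,128,139
LD,nonparametric,strong,184,179,188
VS,nonparametric,strong,72,69,75
CL,nonparametric,strong,145,140,150
ML,nonparametric,strong,82,77,87
MM,nonparametric,strong,241,236,246
FL,nonparametric,strong,168,162,174
RZ,nonparametric,strong,126,123,131
LF,nonparametric,strong,191,185,198
SE,nonparametric,strong,177,172,182
ER,nonparametric,difference,34,25,41
LD,nonparametric,difference,25,18,32
VS,nonparametric,difference,-3,-8,3
CL,nonparametric,difference,35,28,41
ML,nonparametric,difference,22,15,29
MM,nonparametric,difference,61,54,69
FL,nonparametric,difference,50,43,58
RZ,nonparametric,difference,-3,-11,2
LF,nonparametric,difference,105,97,116
SE,nonparametric,difference,-22,-28,-15
ER,parametric_c_su,weak,178,170,186
LD,parametric_c_su,weak,212,206,218
VS,parametric_c_su,weak,68,64,72
CL,parametric_c_su,weak,182,177,189
ML,parametric_c_su,weak,108,102,115
MM,parametric_c_su,weak,345,333,359
FL,parametric_c_su,weak,248,239,257
RZ,parametric_c_su,weak,122,116,127
LF,parametric_c_su,weak,390,378,400
SE,parametric_c_su,weak,156,151,160
ER,parametric_c_su,strong,135,128,140
LD,parametric_c_su,strong,185,180,190
VS,parametric_c_su,strong,71,68,75
CL,parametric_c_su,strong,145,140,150
ML,parametric_c_su,strong,84,78,89
MM,parametric_c_su,strong,250,243,257
FL,parametric_c_su,strong,180,173,188
RZ,parametric_c_su,strong,125,120,130
LF,parametric_c_su,strong,211,200,220
SE,parametric_c_su,strong,177,172,182
ER,parametric_c_su,difference,43,33,54
LD,parametric_c_su,difference,27,19,35
VS,parametric_c_su,difference,-3,-9,2
CL,parametric_c_su,difference,37,29,46
ML,parametric_c_su,difference,24,16,33
MM,parametric_c_su,difference,95,82,111
FL,parametric_c_su,difference,68,55,79
RZ,parametric_c_su,difference,-3,-10,4
LF,parametric_c_su,difference,179,164,195
SE,parametric_c_su,difference,-21,-28,-15
ER,parametric_c_o,weak,265,251,281
LD,parametric_c_o,weak,219,213,226
VS,parametric_c_o,weak,84,79,89
CL,parametric_c_o,weak,191,186,199
ML,parametric_c_o,weak,141,129,152
MM,parametric_c_o,weak,376,360,392
FL,parametric_c_o,weak,301,289,316
RZ,parametric_c_o,weak,138,132,144
LF,parametric_c_o,weak,422,407,437
SE,parametric_c_o,weak,163,158,169
ER,parametric_c_o,strong,188,179,197
LD,parametric_c_o,strong,189,184,194
VS,parametric_c_o,strong,77,74,81
CL,parametric_c_o,strong,154,148,161
ML,parametric_c_o,strong,108,99,117
MM,parametric_c_o,strong,304,294,316
FL,parametric_c_o,strong,195,185,205
RZ,parametric_c_o,strong,135,130,140
LF,parametric_c_o,strong,311,295,328
SE,parametric_c_o,strong,184,178,189
ER,parametric_c_o,difference,77,61,95
LD,parametric_c_o,difference,30,22,38
VS,parametric_c_o,difference,7,1,13
CL,parametric_c_o,difference,37,29,46
ML,parametric_c_o,difference,33,17,47
MM,parametric_c_o,difference,72,52,90
FL,parametric_c_o,difference,106,90,123
RZ,parametric_c_o,difference,3,-6,11
LF,parametric_c_o,difference,111,89,133
SE,parametric_c_o,difference,-21,-27,-13
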