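variant,distribution,assay,polyphen_score,polyphen_prediction,treesaap_cat8_properties,treesaap_cat67_properties
M-1-T,Middle,-,,benign,,
P-5-L,Middle,-,,benign,"alpha_c,alpha_n","K0,Hp"
E-40-K,Significant,-,1.424,benign,pHi,
M-41-I,NonSig,-,1.16,benign,,
S-67-R,Middle,-,1.563,possibly damaging,,
R-72-L,Middle,-,1.958,possibly damaging,"H,Hnc",alpha_n
E-167-K,Low,LPL Inhib,0.194,benign,pHi,
P-174-S,Middle,-,1.715,possibly damaging,,
E-190-Q,NonSig,-,0.243,benign,,
E-196-K,Middle,-,1.541,possibly damaging,pHi,El
G-223-R,Low,Secretion,2.065,probably damaging,Esm,
R-230-C,Middle,-,2.792,probably damaging,"pHi,Esm,Et,Br","Ns,C"
F-237-V,Middle,-,2.51,probably damaging,,
P-251-T,High,Nothing,1.781,possibly damaging,,
T-266-M,NonSig,-,0.783,benign,,"K0,Ht"
R-278-Q,Significant,-,0.644,benign,,pHi
V-291-M,Middle,-,1.012,benign,,
L-293-M,Middle,-,1.236,benign,,
E-296-V,Middle,-,2.057,probably damaging,"Ns,Pbeta","Br,H,Ra"
P-307-S,Middle,-,0.955,benign,,alpha_c
V-308-M,Middle,-,1.199,benign,,
R-336-C,Low,Secretion,2.255,probably damaging,"Br,pHi,Et","Ns,C,Ca,Hnc"
D-338-E,Middle,-,1.626,possibly damaging,,
W-349-C,Low,Secretion,3.677,probably damaging,,
G-361-R,Low,Secretion,2.274,probably damaging,"Ca,Esm","Mv,Mw,Hnc,V0,mu"
R-371-Q,High,Nothing,1.558,possibly damaging,,pHi
R-384-W,Low,Secretion,2.304,probably damaging,,"Br,Ht"
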