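# Reference table of tumor/cyst-elevated negative-mode ions with tentative identities.
# formula: as printed (underscore dialect); formula_is_ion: whether the printed formula
# is the ion (True) or the neutral molecule (False).
# serum_overlap: feature also present in the curated UPLC-MS serum list (dagger flag).
# note records rows whose printed theo/ppm disagree with recomputation from atomic masses.
exp_mz,formula,theo_mz_printed,ppm_printed,adduct,identity,serum_overlap,formula_is_ion,note
436.2826,C_21_H_43_NO_6_P,436.2834,1.8,[M-H]-,LPE(P-16:0),True,True,computed theo 436.2833; printed ppm follows printed theo
464.3139,C_23_H_47_NO_6_P,464.3147,1.7,[M-H]-,"LPE(O-18:1), LPE(P-18:0)",False,True,computed theo 464.3146 (last-digit rounding)
465.3054,C_27_H_46_O_4_S,465.3044,1.3,[M-H]-,Cholesterol Sulfate,True,False,printed ppm 1.3 not reproducible (computed 2.1)
480.3091,C_23_H_47_NO_7_P,480.3096,0.8,[M-H]-,LPE(18:0),True,True,printed ppm 0.8 not reproducible (computed 1.0)
524.2975,C_24_H_47_NO_9_P,524.2994,3.6,[M-H]-,LPS(18:0),True,True,
536.5044,C_34_H_66_NO_3_,536.5048,0.9,[M-H]-,Cer(d34:1),True,True,printed ppm 0.9 not reproducible (computed 0.8)
572.4827,C_34_H_67_NO_3_Cl,572.4815,2.1,[M+Cl]-,Cer(d34:1),False,True,
583.2567,C_33_H_36_N_4_O_6_,583.2562,0.3,[M-H]-,Bilirubin,True,False,printed ppm 0.3 not reproducible (computed 0.8); serum discriminatory marker
599.3209,C_27_H_52_O_12_P,599.3202,1.2,[M-H]-,LPI(18:0),True,True,
626.5328,C_38_H_73_NO_3_Cl,626.5285,6.8,[M+Cl]-,Cer(d38:2),False,True,computed theo 626.5284; printed ppm 6.8 not reproducible (computed 6.9)
646.6124,C_42_H_80_NO_3_,646.6144,3.1,[M-H]-,Cer(d42:2),False,True,printed ppm 3.1 not reproducible (computed 3.0)
648.6272,C_42_H_82_NO_3_,648.6300,5.9,[M-H]-,Cer(d42:1),False,True,printed ppm 5.9 not reproducible (computed 4.3)
656.5800,C_40_H_79_NO_3_Cl,656.5754,7.0,[M+Cl]-,Cer(d40:1),False,True,
658.5919,C_40_H_81_NO_3_Cl,658.5910,1.5,[M+Cl]-,Cer(d40:0),False,True,printed ppm 1.5 not reproducible (computed 1.3)
682.5891,C_42_H_81_NO_3_Cl,682.5911,2.9,[M+Cl]-,Cer(d42:2),False,True,computed theo 682.5910; companion text also prints 682.5911
684.5952,C_42_H_83_NO_3_Cl,684.6061,15.9,[M+Cl]-,Cer(d42:1),False,True,table theo 684.6061 conflicts with companion text 684.6067; computed value matches the text
737.5318,C_39_H_79_N_2_O_6_P,737.5369,6.9,[M+Cl]-,SM(d34:1),True,False,printed formula lacks Cl (neutral); computed theo 737.5370
847.6430,C_47_H_93_N_2_O_6_PCl,847.6465,4.1,[M+Cl]-,SM(d42:2),False,True,printed ppm 4.1 not reproducible (computed 4.2)
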