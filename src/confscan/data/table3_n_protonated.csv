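name,mp2_label,E_mp2_avdz,E_cc_dz_mp2geom,E_cc_dz,E_cc_tz,E_cc_qz_f12a,E_cc_qz_f12b,d_core,d_rel,d_T,d_Q,e_e,zpe,h0,h298,g298
,,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol
I_N,N1,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
II_N,N2,0.52,0.52,0.54,0.56,0.55,0.55,0.01,0.00,0.00,0.00,0.56,0.06,0.62,0.69,0.54
III_N,N3,1.27,1.45,1.44,1.39,1.38,1.39,0.00,0.01,0.00,0.00,1.40,-0.14,1.27,1.37,1.04
IV_N,N4,1.62,1.73,1.75,1.71,1.70,1.71,0.01,0.01,0.00,0.00,1.73,-0.06,1.67,1.83,1.36
V_N,N5,2.77,3.16,3.19,3.20,3.20,3.20,0.00,0.00,-0.01,-0.01,3.18,0.00,3.18,3.19,3.20
VI_N,N6,4.07,4.40,4.38,4.43,4.42,4.43,0.02,0.00,-0.01,-0.02,4.41,-0.06,4.35,4.48,4.01
VII_N,N7,4.46,4.94,4.96,4.93,4.93,4.93,0.01,0.00,-0.01,-0.01,4.90,-0.15,4.76,4.88,4.55
VIII_N,N8,5.27,5.69,5.68,5.67,5.67,5.67,0.02,0.00,-0.01,-0.02,5.67,-0.18,5.49,5.72,4.96
IX_N,N10,7.56,7.15,7.17,7.18,7.19,7.20,0.06,-0.01,0.01,0.01,7.27,-0.14,7.14,7.32,6.73
X_N,N9,7.54,7.31,7.31,7.31,7.32,7.33,0.07,-0.01,0.01,0.00,7.39,-0.18,7.21,7.44,6.33
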