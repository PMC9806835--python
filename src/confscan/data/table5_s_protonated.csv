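name,mp2_label,E_mp2_avdz,E_cc_dz_mp2geom,E_cc_dz,E_cc_tz,E_cc_qz_f12a,E_cc_qz_f12b,d_core,d_rel,d_T,d_Q,e_e,zpe,h0,h298,g298
,,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol
I_S,S1,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
II_S,S3,1.97,0.66,0.81,0.83,0.79,0.79,0.03,0.01,-0.02,0.06,0.86,0.84,1.70,2.14,2.03
III_S,S2,1.94,0.40,1.11,1.15,1.11,1.11,0.02,0.00,-0.01,0.03,1.14,0.87,2.01,1.81,1.76
IV_S,S4,3.29,1.72,2.14,2.13,2.08,2.08,0.03,0.03,-0.03,0.05,2.17,0.61,2.78,3.11,1.77
V_S,S5,3.44,2.17,2.49,2.48,2.44,2.43,0.01,0.03,-0.02,0.02,2.48,0.66,3.13,3.31,2.62
VI_S,S6,4.44,2.66,3.06,3.03,2.98,2.98,0.05,0.04,-0.03,0.07,3.11,0.78,3.88,4.00,3.64
VII_S,S7,4.52,2.71,3.12,3.07,3.03,3.02,0.05,0.05,-0.03,0.07,3.16,0.70,3.86,3.94,3.75
VIII_S,S9,5.71,4.69,4.01,3.98,3.95,3.94,0.04,0.03,-0.06,0.04,4.00,1.18,5.18,6.19,6.69
IX_S,S10,6.15,3.63,4.68,4.66,4.62,4.61,0.06,0.00,-0.04,0.05,4.69,0.78,5.47,4.99,4.51
X_S,S8,5.32,4.26,5.03,5.07,5.04,5.04,0.03,0.00,-0.01,-0.03,5.03,0.69,5.72,5.40,5.22
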