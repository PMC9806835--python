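name,mp2_label,E_mp2_avdz,E_cc_dz_mp2geom,E_cc_dz,E_cc_tz,E_cc_qz_f12a,E_cc_qz_f12b,d_core,d_rel,d_T,d_Q,e_e,zpe,h0,h298,g298
,,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol
I,1,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
II,2,1.48,1.48,1.49,1.53,1.53,1.53,0.01,-0.01,0.00,-0.01,1.52,-0.06,1.46,1.58,1.32
III,3,1.63,1.63,1.61,1.62,1.61,1.60,0.03,-0.02,0.02,0.02,1.66,-0.50,1.16,1.42,0.43
IV,4,1.71,1.75,1.74,1.75,1.74,1.74,0.04,-0.02,0.02,0.03,1.81,-0.44,1.37,1.62,0.72
V,5,1.81,1.78,1.78,1.81,1.80,1.80,0.04,-0.01,0.03,0.02,1.87,-0.44,1.43,1.68,0.81
VI,7,1.98,1.95,1.95,1.95,1.94,1.94,0.04,-0.01,0.03,0.02,2.03,-0.28,1.75,1.86,1.26
VII,6,1.97,1.95,1.95,1.96,1.95,1.95,0.01,0.00,0.03,0.03,2.02,-0.55,1.46,1.65,1.11
VIII,8,2.27,2.10,2.10,2.11,2.11,2.11,0.01,-0.02,-0.01,0.01,2.09,-0.15,1.94,2.08,1.73
IX,10,2.54,2.15,2.17,2.19,2.19,2.19,0.02,-0.01,0.00,0.00,2.20,-0.27,1.93,2.54,1.90
X,9,2.39,2.54,2.55,2.58,2.58,2.58,0.05,-0.01,0.04,0.00,2.66,-0.36,2.30,2.13,1.31
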