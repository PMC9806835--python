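name,mp2_label,E_mp2_avdz,E_cc_dz_mp2geom,E_cc_dz,E_cc_tz,E_cc_qz_f12a,E_cc_qz_f12b,d_core,d_rel,d_T,d_Q,e_e,zpe,h0,h298,g298
,,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol
I_O,O1,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
II_O,O2,1.00,1.12,1.12,1.07,1.07,1.07,0.00,0.01,0.01,0.00,1.09,-0.08,1.01,1.07,0.83
III_O,O3,6.63,6.71,6.76,6.81,6.83,6.82,0.04,0.00,0.01,0.05,6.91,-0.70,6.21,6.24,5.91
IV_O,O4,7.25,7.19,7.28,7.27,7.26,7.26,0.04,0.01,0.00,0.02,7.32,-0.35,6.97,7.05,6.80
V_O,O6,7.84,7.46,7.56,7.57,7.56,7.55,0.04,0.01,-0.01,0.06,7.65,-0.61,7.04,7.34,7.01
VI_O,O7,7.93,7.55,7.65,7.66,7.66,7.65,0.04,0.00,0.00,0.07,7.76,-0.55,7.21,7.15,6.83
VII_O,O5,7.62,7.70,7.78,7.78,7.79,7.79,0.04,0.00,0.01,0.05,7.88,-0.54,7.34,7.29,6.72
VIII_O,O8,8.24,7.84,7.91,7.91,7.90,7.89,0.05,0.00,-0.01,0.06,7.99,-0.51,7.48,7.58,7.13
IX_O,O9,8.34,7.89,7.98,7.97,7.96,7.95,0.02,0.02,-0.01,0.07,8.05,-0.41,7.63,7.81,7.31
X_O,O10,8.43,8.51,8.60,8.54,8.53,8.53,0.04,0.02,0.00,0.02,8.60,-0.51,8.09,8.25,7.78
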