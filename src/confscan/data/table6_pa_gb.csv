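pair,E_qz,d_T,d_Q,d_core,d_rel,e_e,zpe,h0,h298,g298
,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol,kcal/mol
I-I_N,222.89,-0.03,-0.01,0.10,0.03,222.98,-8.49,214.49,215.79,208.44
I-I_O,208.57,0.02,-0.04,0.05,0.02,208.62,-7.45,201.17,202.74,194.56
I-I_S,198.22,-0.03,0.01,-0.06,0.05,198.18,-5.46,192.72,194.02,186.86
average_N,223.60,-0.03,-0.01,0.10,0.04,223.69,-8.73,214.96,216.39,208.21
average_O,209.47,0.02,-0.04,0.04,0.02,209.51,-7.67,201.83,203.55,194.16
average_S,199.13,-0.04,0.02,-0.06,0.06,199.10,-5.79,193.31,194.74,186.40
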