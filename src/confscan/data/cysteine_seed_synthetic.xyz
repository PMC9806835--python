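14
synthetic cysteine seed (RDKit ETKDG + MMFF94); stand-in for a literature global-minimum geometry
N     -0.386492     1.414488     0.841365
C      0.030110     0.342051    -0.091542
C     -0.823151    -0.921503     0.101137
S     -2.596042    -0.627916    -0.248436
C      1.525533     0.055707     0.104046
O      2.369701     0.854179     0.485863
O      1.908888    -1.176800    -0.282758
H     -1.348051     1.683577     0.633766
H      0.203924     2.234028     0.691692
H     -0.076740     0.710434    -1.119512
H     -0.496118    -1.721887    -0.570536
H     -0.731629    -1.298368     1.126140
H     -2.455844    -0.369106    -1.556682
H      2.875911    -1.178885    -0.114542
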