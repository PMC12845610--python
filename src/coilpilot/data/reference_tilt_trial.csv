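Trial,RobotPitchAngle,TotalLoad,NormCh0,NormCh1,MEP_uV
A3,21,1867,0.37,0.63,492.47
A3,22,1777,0.41,0.59,434.43
A3,23,1863,0.46,0.54,834.70
A3,24,1769,0.48,0.52,1861.40
A3,25,1669,0.52,0.48,1067.20
A3,26,1731,0.52,0.48,748.72
A3,27,1795,0.55,0.45,1108.10
A3,28,1752,0.58,0.42,483.87
A3,29,1741,0.61,0.39,572.38
A3,30,1614,0.69,0.31,367.76
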