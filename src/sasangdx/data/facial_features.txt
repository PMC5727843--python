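# Candidate facial feature variables, one per line.
# F* = frontal view, P* = profile view; numbers are landmark point ids.
# Named areas (FArea02, FArea03) are polygons defined in face_polygons.yaml.

# -- face shape: size --
FD_43_143
FD_53_153
FD_94_194
FDH_33_133
PDH_44_53
PDH_12_36
PDH_14_36
PDH_21_36
FDV_47_52
FDV_47_50
FDV_10_21
FDV_52_50
FDV_81_50
PDV_6_12
PDV_6_32
PDV_10_32
PDV_12_32
PDV_21_32
PDV_25_32
FArea02
FArea03
FArea02/FArea03

# -- face shape: shape --
FA_53_94
FAs_153_194
FA_94_43
FAs_194_143
FA_53_94_43
FA_18_25_43
FA_118_125_143
FA_18_17_43
FA_118_117_143
FA_17_25_43
FA_117_125_143
FA_18_25_94
FA_18_43_50
FA_18_94_50
FHD_33_133_43_143
FDD_53_153_43_143
FDD_94_194_43_143
FHD_33_133_53_153
FVV_47_52_52_81
FVV_47_52_52_50
FVV_47_52_81_50
FVV_52_81_81_50
PVV_6_10_10_33
PVV_12_14_14_32
PVV_12_21_14_32
FVD_52_50_53_153
FVD_52_81_53_153
FVD_81_50_94_194

# -- forehead --
FDV_47_10
PDV_6_9
PDV_6_10
PAi_7_6
PAi_9_7
PAi_71_72
PAi_72_73
PA_6_7_9
PDD_77_9_6_9
PDH_6_7
PDH_9_12
PD_7_77
PDV_6_7
PDV_7_9
PDV_9_12
PA_9_12
PA_10_12

# -- eye --
FDH_18_25
FDH_118_125
FDH_18_118
FDH_25_125
FDH_21_121
FA_18_17_25
FA_118_117_125
FAi_25_17
FAis_125_117
FAis_18_17
FAi_118_117
FAis_18_25
FAi_118_125
FD_17_26
FD_117_126
FDH_17_26_18_25
FDH_117_126_118_125
FDH_52_50_18_118
FDD_17_26_52_81
FDD_17_26_52_50
(FDH_18_25+FDH_118_125)/2/FDH_18_118
(FDH_18_25+FDH_118_125)/2/FD_53_153
(FDH_18_25+FDH_118_125)/2/FDH_33_133
FHD_18_118_53_153
FHD_25_125_53_153
FD_17_25
FD_117_125
FD_18_25
FD_118_125

# -- nose --
FDH_36_136
PDH_12_14
PDL_14_12_21
PAi_14_12
PA_14_21
PA_12_14_21
PAi_13_84
PA_87_88
PA_87_21
FDV_52_81
PDV_12_14
PDV_14_21
PDV_12_21
PD_12_21
PDH_41_21
FHD_36_136_53_153
FVH_52_81_36_136
FArea_52_36_136
PArea_12_14_21

# -- mouth --
PDL_22_21_32
PDL_25_21_32
FVV_80_50_52_50
FVV_80_50_81_50
FDV_80_50

# -- chin --
PDH_32_36
PA_32_33
PA_33_36
PA_32_33_36
PDV_32_36
PD_32_36
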