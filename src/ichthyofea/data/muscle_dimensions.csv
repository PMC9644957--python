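specimen,muscle,length_mm,volume_mm3
M1409,mAMEpr,72,2085
M1409,mAMEsu,60,1599
M1409,mAMEme,62,1227
M1409,mAMIps,73,1461
M1409,mAMIpt,55,1648
M1409,mAMP,54,794
M1409,mDM,45,1595
M1399,mAMEpr,83,1556
M1399,mAMEsu,62,2515
M1399,mAMEme,77,2094
M1399,mAMIps,85,2660
M1399,mAMIpt,37,1591
M1399,mAMP,54,1950
M1399,mDM,57,7214
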