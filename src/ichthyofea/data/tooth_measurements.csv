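specimen,tooth,length_mm,diameter_mm
M1409,1,11.9,2.2
M1409,2,10.2,4
M1409,3,9.5,2.4
M1409,4,8.8,1.6
M1409,5,9.5,1.8
M1409,6,10.5,1.7
M1409,7,9,2
M1409,8,8.4,5.6
M1409,9,7,1.9
M1409,10,11.1,2.6
M1399,1,7.3,3.3
M1399,2,6.8,2.3
M1399,3,9.8,2.7
M1399,4,5.3,2
M1399,5,8.8,3.7
M1399,6,7.2,2.8
M1399,7,7.4,2.4
M1399,8,6.3,2.1
M1399,9,4.9,2.3
M1399,10,8.4,2.5
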