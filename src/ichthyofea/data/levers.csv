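specimen,mechanical_advantage_tip,out_lever_tip_mm,out_lever_back_mm,out_lever_back_source
M1409,0.089,401.0,82.908,implied
M1399,0.191,335.0,102.916,implied
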