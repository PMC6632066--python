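material,test,experimental_value,unit
amlodipine besylate,bfe,209.0,mJ
SMCC 90,bfe,235.0,mJ
PVP K25,bfe,121.0,mJ
CCM-Na,bfe,341.0,mJ
St-Mg,bfe,16.7,mJ
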