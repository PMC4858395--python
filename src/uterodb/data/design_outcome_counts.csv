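design,n_active,n_inactive
Imm_Rat_Inj,147,57
Imm_Rat_Oral,61,20
OVX_Rat_Inj,29,3
OVX_Rat_Oral,5,5
OVX_Mouse_Inj,11,14
OVX_Mouse_Oral,6,16
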