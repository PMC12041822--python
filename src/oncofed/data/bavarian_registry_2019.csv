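entity_group,count
breast,11260
prostate,8590
colorectum,8100
lung,5821
melanoma,3400
bladder,3253
cervix,3030
pancreas,2214
non_hodgkin_lymphoma,2133
stomach,2023
other,13947
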