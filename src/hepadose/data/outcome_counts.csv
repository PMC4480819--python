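cell_type,responders_3m,evaluable_3m,responders_6m,evaluable_6m,grade34,evaluable_tox,reild,patients
HCC,9,15,7,10,10,22,2,26
CCA,2,11,2,5,2,16,1,18
NET,8,14,6,13,1,19,0,20
CRC,5,19,3,10,5,28,1,29
other,6,15,3,6,6,26,1,29
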