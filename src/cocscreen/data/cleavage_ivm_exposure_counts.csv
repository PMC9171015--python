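group,category,count
control,uncleaved,58
control,<=8-cell,103
control,>8-cell,116
vehicle,uncleaved,64
vehicle,<=8-cell,114
vehicle,>8-cell,104
DES 1e-9 M,uncleaved,82
DES 1e-9 M,<=8-cell,85
DES 1e-9 M,>8-cell,116
DES 1e-7 M,uncleaved,74
DES 1e-7 M,<=8-cell,104
DES 1e-7 M,>8-cell,103
DES 1e-5 M,uncleaved,88
DES 1e-5 M,<=8-cell,114
DES 1e-5 M,>8-cell,73
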