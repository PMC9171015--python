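group,category,count
control,uncleaved,47
control,<=8-cell,106
control,>8-cell,87
vehicle,uncleaved,45
vehicle,<=8-cell,99
vehicle,>8-cell,95
DES 1e-9 M,uncleaved,43
DES 1e-9 M,<=8-cell,97
DES 1e-9 M,>8-cell,100
DES 1e-7 M,uncleaved,50
DES 1e-7 M,<=8-cell,86
DES 1e-7 M,>8-cell,104
DES 1e-5 M,uncleaved,31
DES 1e-5 M,<=8-cell,102
DES 1e-5 M,>8-cell,97
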