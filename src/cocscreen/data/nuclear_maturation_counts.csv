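group,category,count
control,MII,72
control,abnormal,18
vehicle,MII,76
vehicle,abnormal,14
DES 1e-9 M,MII,72
DES 1e-9 M,abnormal,16
DES 1e-7 M,MII,81
DES 1e-7 M,abnormal,20
DES 1e-5 M,MII,3
DES 1e-5 M,abnormal,94
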