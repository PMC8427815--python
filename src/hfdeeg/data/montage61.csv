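label,x,y
Fp1,-0.3192,0.9100
Fpz,0.0012,0.9298
Fp2,0.3201,0.9097
AF7,-0.6175,0.7721
AF3,-0.3107,0.7084
AFz,0.0019,0.6768
AF4,0.3221,0.7011
AF8,0.6177,0.7719
F7,-0.8552,0.5170
F5,-0.6392,0.4763
F3,-0.4209,0.4449
F1,-0.2056,0.4258
Fz,0.0023,0.4221
F2,0.2205,0.4304
F4,0.4331,0.4538
F6,0.6500,0.4769
F8,0.8544,0.5196
FT7,-0.9825,0.1717
FC5,-0.7230,0.1746
FC3,-0.4696,0.1773
FC1,-0.2286,0.1746
FCz,0.0024,0.1752
FC2,0.2356,0.1791
FC4,0.4783,0.1822
FC6,0.7266,0.1821
FT8,0.9803,0.1847
T7,-0.9647,-0.1836
C5,-0.7071,-0.1212
C3,-0.4610,-0.0821
C1,-0.2231,-0.0616
Cz,0.0023,-0.0533
C2,0.2347,-0.0600
C4,0.4727,-0.0768
C6,0.7154,-0.1095
T8,0.9675,-0.1708
TP7,-0.8448,-0.4583
CP5,-0.6294,-0.3681
CP3,-0.4127,-0.3053
CP1,-0.2018,-0.2687
CPz,0.0021,-0.2597
CP2,0.2180,-0.2674
CP4,0.4273,-0.2992
CP6,0.6416,-0.3550
TP8,0.8486,-0.4518
P7,-0.6548,-0.6640
P5,-0.5022,-0.5695
P3,-0.3389,-0.5038
P1,-0.1660,-0.4670
Pz,0.0018,-0.4539
P2,0.1823,-0.4597
P4,0.3515,-0.4960
P6,0.5074,-0.5673
P8,0.6596,-0.6597
PO7,-0.4430,-0.7879
PO3,-0.2463,-0.6802
POz,0.0014,-0.6496
PO4,0.2492,-0.6833
PO8,0.4479,-0.7855
O1,-0.2212,-0.8456
Oz,0.0008,-0.8443
O2,0.2248,-0.8448
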