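biome,b_leaf,b_wood,b_froot,b_croot,LN,Lleaf,Lfroot,Lwood,c_1,c_2,c_3,c_4,c_5,c_6,c_7,c_8,c_9,c_10,c_11,c_12,c_13
ENF,0.25,0.40,0.25,0.10,35.0,0.24,0.22,0.35,0.26,0.030,0.60,0.040,14.8,3.9,18.5,4.9,0.25,6.0,7.3,0.20,0.0045
EBF,0.30,0.35,0.25,0.10,30.0,0.20,0.20,0.38,0.50,0.045,0.70,0.055,14.8,3.9,18.5,4.9,0.30,6.0,7.3,0.20,0.0045
DNF,0.30,0.38,0.22,0.10,32.0,0.22,0.22,0.35,1.00,0.032,0.60,0.042,14.8,3.9,18.5,4.9,0.25,6.0,7.3,0.20,0.0045
DBF,0.20,0.50,0.20,0.10,28.0,0.18,0.20,0.36,1.00,0.014,0.60,0.020,14.8,3.9,18.5,4.9,0.20,6.0,7.3,0.20,0.0045
MF,0.25,0.42,0.23,0.10,30.0,0.21,0.21,0.36,0.60,0.025,0.60,0.035,14.8,3.9,18.5,4.9,0.25,6.0,7.3,0.20,0.0045
CSH,0.35,0.12,0.43,0.10,22.0,0.18,0.18,0.32,1.00,0.25,0.80,0.25,14.8,3.9,18.5,4.9,0.40,6.0,7.3,0.20,0.0045
OSH,0.35,0.12,0.43,0.10,22.0,0.18,0.18,0.32,1.00,0.28,0.80,0.28,14.8,3.9,18.5,4.9,0.40,6.0,7.3,0.20,0.0045
GRA,0.45,0.01,0.53,0.01,16.0,0.14,0.16,0.30,1.00,0.50,0.80,0.50,14.8,3.9,18.5,4.9,0.40,6.0,7.3,0.20,0.0045
WET,0.40,0.05,0.50,0.05,18.0,0.15,0.16,0.30,1.00,0.30,0.80,0.35,14.8,3.9,18.5,4.9,0.40,6.0,7.3,0.20,0.0045
CRO,0.50,0.01,0.48,0.01,14.0,0.12,0.14,0.28,1.00,0.50,0.90,0.50,14.8,3.9,18.5,4.9,0.40,6.0,7.3,0.15,0.0045
CRN,0.45,0.05,0.45,0.05,16.0,0.13,0.15,0.29,1.00,0.40,0.85,0.45,14.8,3.9,18.5,4.9,0.40,6.0,7.3,0.20,0.0045
BAR,0.50,0.01,0.48,0.01,18.0,0.15,0.16,0.30,1.00,0.50,0.80,0.50,14.8,3.9,18.5,4.9,0.40,6.0,7.3,0.20,0.0045
TUN,0.50,0.02,0.46,0.02,20.0,0.16,0.17,0.30,0.80,0.30,0.70,0.35,14.8,3.9,18.5,4.9,0.35,6.0,7.3,0.20,0.0045
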