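code1,code3,polarity_raw,polarity_printed,hydrophobicity_raw,hydrophobicity_printed,volume_raw,volume_printed,isoelectric_raw,isoelectric_printed
A,Ala,7.0,-0.1672,1.8,0.7638,31,-1.067,6.00,-0.02972
C,Cys,4.8,-1.043,2.5,1.002,55,-0.5477,5.07,-0.5561
D,Asp,13.0,2.221,-3.5,-1.039,54,-0.5694,2.77,-1.858
E,Glu,12.5,2.022,-3.5,-1.039,8.3,-1.559,3.22,-1.603
F,Phe,5.0,-0.9631,2.8,1.104,132,1.120,5.48,-0.3241
G,Gly,7.9,0.1910,-0.4,0.01531,3,-1.674,5.97,-0.0467
H,His,8.4,0.3900,-3.2,-0.9373,96,0.3402,7.59,0.8703
I,Ile,4.9,-1.003,4.5,1.682,111,0.6651,6.02,-0.0184
K,Lys,10.1,1.067,-3.0,-0.8693,119,0.8384,9.74,2.087
L,Leu,4.9,-1.027,3.8,1.444,111,0.6651,5.98,-0.04104
M,Met,5.3,-0.8437,1.9,0.7978,105,0.5352,5.74,-0.1769
N,Asn,10.0,1.027,-3.5,-1.039,56,-0.5261,5.41,-0.3637
P,Pro,6.6,-0.3264,-1.6,-0.3930,32.5,-1.035,6.30,0.1401
Q,Gln,8.6,0.4696,-3.5,-1.039,85,0.102,5.65,-0.2278
R,Arg,9.1,0.6686,-4.5,-1.380,124,0.9466,10.76,2.665
S,Ser,7.5,0.03184,-0.8,-0.1208,32,-1.046,5.68,-0.2108
T,Thr,6.6,-0.3264,-0.7,-0.08676,61,-0.4178,6.16,0.06085
V,Val,5.6,-0.7243,4.2,1.580,84,0.08035,5.96,-0.05236
W,Trp,5.2,-0.8835,-0.9,0.1548,170,1.943,5.89,-0.09198
X,Stop,,-1.5993,,1.672,,-1.5833,,-2.6562
Y,Tyr,5.4,-0.8039,-1.3,0.2909,136,1.207,5.66,-0.2222
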