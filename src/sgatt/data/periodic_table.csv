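symbol,period,group,metallicity,radius_pm,weight
H,1,1,nonmetal,31,1.008
He,1,18,nonmetal,28,4.0026
Li,2,1,metal,128,6.94
Be,2,2,metal,96,9.0122
B,2,13,metalloid,84,10.81
C,2,14,nonmetal,76,12.011
N,2,15,nonmetal,71,14.007
O,2,16,nonmetal,66,15.999
F,2,17,nonmetal,57,18.998
Ne,2,18,nonmetal,58,20.180
Na,3,1,metal,166,22.990
Mg,3,2,metal,141,24.305
Al,3,13,metal,121,26.982
Si,3,14,metalloid,111,28.085
P,3,15,nonmetal,107,30.974
S,3,16,nonmetal,105,32.06
Cl,3,17,nonmetal,102,35.45
Ar,3,18,nonmetal,106,39.948
K,4,1,metal,203,39.098
Ca,4,2,metal,176,40.078
Ti,4,4,metal,160,47.867
Cr,4,6,metal,139,51.996
Mn,4,7,metal,139,54.938
Fe,4,8,metal,132,55.845
Co,4,9,metal,126,58.933
Ni,4,10,metal,124,58.693
Cu,4,11,metal,132,63.546
Zn,4,12,metal,122,65.38
Ga,4,13,metal,122,69.723
Ge,4,14,metalloid,120,72.630
As,4,15,metalloid,119,74.922
Se,4,16,nonmetal,120,78.971
Br,4,17,nonmetal,120,79.904
Kr,4,18,nonmetal,116,83.798
Rb,5,1,metal,220,85.468
Sr,5,2,metal,195,87.62
Ag,5,11,metal,145,107.87
Cd,5,12,metal,144,112.41
Sn,5,14,metal,139,118.71
Sb,5,15,metalloid,139,121.76
Te,5,16,metalloid,138,127.60
I,5,17,nonmetal,139,126.90
Xe,5,18,nonmetal,140,131.29
Cs,6,1,metal,244,132.91
Ba,6,2,metal,215,137.33
Pt,6,10,metal,136,195.08
Au,6,11,metal,136,196.97
Hg,6,12,metal,132,200.59
Pb,6,14,metal,146,207.2
Bi,6,15,metal,148,208.98
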