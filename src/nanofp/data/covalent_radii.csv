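# Single-bond covalent radii (Angstrom), Cordero et al. 2008, version 1.
# element,atomic_number,radius_angstrom
H,1,0.31
B,5,0.84
C,6,0.76
N,7,0.71
O,8,0.66
F,9,0.57
Na,11,1.66
Mg,12,1.41
Al,13,1.21
Si,14,1.11
P,15,1.07
S,16,1.05
Cl,17,1.02
K,19,2.03
Ca,20,1.76
Sc,21,1.70
Ti,22,1.60
V,23,1.53
Cr,24,1.39
Mn,25,1.39
Fe,26,1.32
Co,27,1.26
Ni,28,1.24
Cu,29,1.32
Zn,30,1.22
Ga,31,1.22
Ge,32,1.20
Sr,38,1.95
Y,39,1.90
Zr,40,1.75
Nb,41,1.64
Mo,42,1.54
Ag,47,1.45
Cd,48,1.44
In,49,1.42
Sn,50,1.39
Sb,51,1.39
Ba,56,2.15
La,57,2.07
Ce,58,2.04
Hf,72,1.75
Ta,73,1.70
W,74,1.62
Au,79,1.36
Hg,80,1.32
Pb,82,1.46
Bi,83,1.48
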