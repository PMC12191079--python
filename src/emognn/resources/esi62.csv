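label,midline,mirror_of,caudal_partner
FP1,0,FP2,O1
FPZ,1,,OZ
FP2,0,FP1,O2
AF3,0,AF4,CB1
AF4,0,AF3,CB2
F7,0,F8,P7
F5,0,F6,P5
F3,0,F4,P3
F1,0,F2,P1
FZ,1,,PZ
F2,0,F1,P2
F4,0,F3,P4
F6,0,F5,P6
F8,0,F7,P8
FT7,0,FT8,TP7
FC5,0,FC6,CP5
FC3,0,FC4,CP3
FC1,0,FC2,CP1
FCZ,1,,CPZ
FC2,0,FC1,CP2
FC4,0,FC3,CP4
FC6,0,FC5,CP6
FT8,0,FT7,TP8
T7,0,T8,
C5,0,C6,
C3,0,C4,
C1,0,C2,
CZ,1,,
C2,0,C1,
C4,0,C3,
C6,0,C5,
T8,0,T7,
TP7,0,TP8,
CP5,0,CP6,
CP3,0,CP4,
CP1,0,CP2,
CPZ,1,,
CP2,0,CP1,
CP4,0,CP3,
CP6,0,CP5,
TP8,0,TP7,
P7,0,P8,
P5,0,P6,
P3,0,P4,
P1,0,P2,
PZ,1,,
P2,0,P1,
P4,0,P3,
P6,0,P5,
P8,0,P7,
PO7,0,PO8,
PO5,0,PO6,
PO3,0,PO4,
POZ,1,,
PO4,0,PO3,
PO6,0,PO5,
PO8,0,PO7,
CB1,0,CB2,
O1,0,O2,
OZ,1,,
O2,0,O1,
CB2,0,CB1,
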