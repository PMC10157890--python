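sequence,activity_mean,activity_sd,putative_substrate,c_terminal_amide
AFGKacYCR,0.20,0.09,no,true
AFKacWR,0.15,0.06,no,true
QLSKacWP,0.14,0.03,no,true
TGNKacYVP,0.10,0.04,yes,true
GRAKacYWL,0.100,0.009,no,true
GAGKacHVP,0.06,0.03,yes,true
GVGKacYIN,0.055,0.024,no,true
LSGKacGNP,0.042,0.009,yes,true
TDGKacVFQ,0.026,0.024,yes,true
SHLKacAHL,0.024,0.013,no,true
LSGKacEIN,0.024,0.005,no,true
QATKacDAG,0.022,0.006,yes,true
SDKacTI,0.020,0.013,yes,true
SLKacFG,0.020,0.009,no,true
PVKacFI,0.017,0.005,no,true
ISKacFD,0.013,0.007,no,true
SDMKacHWP,0.013,0.009,yes,true
IIDKacSQL,0.011,0.009,yes,true
YFSKacHN,0.010,0.006,yes,false
LDHKacFDL,0.009,0.007,yes,true
GTAKacSVT,,,yes,true
TLSKacLHE,,,yes,true
PSPKacVSD,,,no,true
PEAKacSLL,,,yes,true
FFHKacVNE,,,yes,true
VLEKacLGE,,,yes,true
LISKacIRE,,,yes,true
DLAKacVQR,,,yes,true
PDRKacPFP,,,yes,true
SVRKacGIM,,,yes,true
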