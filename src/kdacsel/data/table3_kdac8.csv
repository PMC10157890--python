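sequence,activity_mean,activity_sd,putative_substrate,c_terminal_amide
QLSKacWP,0.020,0.006,no,true
RMFKacQFN,0.015,0.014,yes,true
SLKacFG,0.0086,0.0017,no,true
GRAKacYWL,0.007,0.003,no,true
ISKacFD,0.0049,0.0014,yes,true
AFKacWR,0.0040,0.0009,no,true
PLWKacGIG,0.0035,0.0021,yes,true
FAKacWR,0.0032,0.0015,no,true
RIPKacEQW,0.0031,0.0015,yes,true
RFTKacCLR,0.0030,0.0016,yes,true
AFGKacYCR,0.0029,0.0004,no,true
PVKacFI,0.0025,0.0005,yes,true
YSKacGF,0.0020,0.0010,yes,true
YQKacWD,0.0018,0.0006,yes,true
FSKacAF,0.0016,0.0006,no,true
TGNKacYVP,0.0011,0.0006,no,true
TGKacTF,0.0011,0.0002,no,true
VIKacGF,0.0009,0.0001,no,true
LGGKacQRA,0.0006,0.0004,yes,true
LHKacLL,0.0004,0.0003,yes,true
LSGKacEIN,,,yes,true
EIGKacTLA,,,yes,true
EVGKacLLN,,,yes,true
SDKacTI,,,yes,true
VGGKacDFE,,,yes,true
GVGKacYIN,,,yes,true
SDMKacHWP,,,no,true
GTAKacSVT,,,no,true
SHLKacAHL,,,no,true
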