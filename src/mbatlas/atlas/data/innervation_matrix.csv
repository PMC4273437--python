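name,g1d,g1main,g2d,g2main,g3d,g3main,g4d,g4main,g5d,g5main,bp1ap,bp1m,bp2a,bp2m,bp2p,b1p,b1s,b1c,b2p,b2s,b2c,ap1ap,ap1m,ap2ap,ap2m,ap3ap,ap3m,a1p,a1s,a1c,a2p,a2s,a2c,a3p,a3s,a3c,pedc
MBON-g5bp2a,N,N,N,N,N,N,N,N,Dd,Dd,N,N,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-b2bp2a,N,N,N,N,N,N,N,N,N,N,N,N,Dd,N,N,N,N,N,Dd,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-bp2mp,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-bp2mp_bilateral,N,N,N,N,N,N,N,N,N,N,N,N,N,Ds,Ds,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-g4>g1g2,Xd,Xd,Xd,Xd,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-b1>a,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,Dd,Dd,N,N,N,N,N,N,N,N,N,Xd,Xd,Xd,Xd,Xd,Xd,Xd,Xd,Xd,N
MBON-a1,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,Dd,Dd,N,N,N,N,N,N,N
MBON-g3,N,N,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-g3bp1,N,N,N,N,Dd,Dd,N,N,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-bp1,N,N,N,N,N,N,N,N,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-g1pedc>ab,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xd,Xd,Xd,Xd,Xd,N,N,N,N,N,N,Xd,Xd,Xd,Xd,Xd,Xd,Xd,Xd,Xd,Dd
MBON-g2ap1,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-ap2,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N
MBON-a3,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,Dd,Dd,N
MBON-ap1,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-ap3ap,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,N,N,N,N,N,N,N,N,N,N,N
MBON-ap3m,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,N,N,N,N,N,N,N,N,N,N
MBON-a2sc,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,Dd,N,N,N,N
MBON-a2p3p,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Dd,N,N,Dd,N,N,N
MBON-g1g2,Ds,Ds,Ds,Ds,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
MBON-g4g5,N,N,N,N,N,N,Dd,Dd,Dd,Dd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-g5,N,N,N,N,N,N,N,N,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-bp2a,N,N,N,N,N,N,N,N,N,N,N,N,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-b2bp2a,N,N,N,N,N,N,N,N,N,N,N,N,Xs,N,N,N,N,N,Xd,Xd,Xs,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-b2,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-bp2p,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-bp2m,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-g4<g1g2,O,O,O,O,N,N,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-g4,N,N,N,N,N,N,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-b1ped,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xs,Xs,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xs
PAM-b1,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-a1,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xd,Xd,N,N,N,N,N,N,N
PAM-g3,N,N,N,N,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-bp1ap,N,N,N,N,N,N,N,N,N,N,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PAM-bp1m,N,N,N,N,N,N,N,N,N,N,N,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PPL1-g1pedc,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd
PPL1-g1,Xs,Xs,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PPL1-g2ap1,N,N,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xd,N,N,N,N,N,N,N,N,N,N,N,N,N,N
PPL1-ap3,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xd,N,N,N,N,N,N,N,N,N,N
PPL1-ap2a2,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xd,N,N,N,N,N,Xd,Xd,Xd,N,N,N,N
PPL1-a3,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,N,Xd,Xd,Xd,N
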