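name,display_name,short_name,cell_class,cells_min,cells_max,count_note,transmitter,dendrite_regions,axon_regions_in_lobes,extralobe_zones,bilateral_dendrites,notes
KC-gd,γd,,KC,75,75,approximate,unknown,,g1d g2d g3d g4d g5d,,False,dendrites in the ventral accessory calyx
KC-gmain,γmain,,KC,600,600,approximate,unknown,,g1main g2main g3main g4main g5main,,False,
KC-apbpap,α′/β′ap,,KC,210,210,approximate,unknown,,ap1ap ap2ap ap3ap bp1ap bp2a bp2p,,False,single axons branch into both β′2a and β′2p
KC-apbpm,α′/β′m,,KC,140,140,approximate,unknown,,ap1m ap2m ap3m bp1m bp2m,,False,
KC-abp,α/βp,,KC,90,90,approximate,unknown,,b1p b2p a1p a2p a3p pedc,,False,dendrites in the dorsal accessory calyx
KC-abs,α/βs,,KC,500,500,approximate,unknown,,b1s b2s a1s a2s a3s pedc,,False,
KC-abc,α/βc,,KC,400,400,approximate,unknown,,b1c b2c a1c a2c a3c pedc,,False,
MBON-g5bp2a,MBON-γ5β′2a,MBON-01,MBON,1,1,,glutamate,g5 bp2a,,SMP CRE,False,
MBON-b2bp2a,MBON-β2β′2a,MBON-02,MBON,1,1,,glutamate,b2 bp2a,,SIP SLP,True,bilateral dendrites in β2 and β′2a
MBON-bp2mp,MBON-β′2mp,MBON-03,MBON,1,1,,glutamate,bp2m bp2p,,CRE SMP,False,
MBON-bp2mp_bilateral,MBON-β′2mp_bilateral,MBON-04,MBON,1,1,,glutamate,bp2m bp2p,,CRE SMP,False,sparse dendrites; dense bilateral axons
MBON-g4>g1g2,MBON-γ4>γ1γ2,MBON-05,MBON,1,1,,glutamate,g4,g1 g2,CRE SMP,False,feedforward axon terminals in γ1 and γ2
MBON-b1>a,MBON-β1>α,MBON-06,MBON,1,1,,glutamate,b1,a1 a2 a3,CRE SMP SIP,False,feedforward axon terminals in the α lobe
MBON-a1,MBON-α1,MBON-07,MBON,2,2,,glutamate,a1,,SIP SLP,False,
MBON-g3,MBON-γ3,MBON-08,MBON,1,1,,GABA,g3,,CRE SMP,True,bilateral dendrites
MBON-g3bp1,MBON-γ3β′1,MBON-09,MBON,1,1,,GABA,g3 bp1,,CRE SMP,True,bilateral dendrites
MBON-bp1,MBON-β′1,MBON-10,MBON,8,8,7-9 across individuals,GABA,bp1,,CRE SMP LAL,False,only MBON projecting to the LAL
MBON-g1pedc>ab,MBON-γ1pedc>α/β,MBON-11,MBON,1,1,,GABA,g1 pedc,a1 a2 a3 b1 b2,CRE SMP,False,feedforward axon terminals across the α/β lobes
MBON-g2ap1,MBON-γ2α′1,MBON-12,MBON,2,2,,acetylcholine,g2 ap1,,CRE SMP,False,
MBON-ap2,MBON-α′2,MBON-13,MBON,1,1,,acetylcholine,ap2,,CRE SMP SIP,False,
MBON-a3,MBON-α3,MBON-14,MBON,2,2,,acetylcholine,a3,,SMP SIP SLP,False,
MBON-ap1,MBON-α′1,MBON-15,MBON,2,2,,acetylcholine,ap1,,SIP SLP LH,False,
MBON-ap3ap,MBON-α′3ap,MBON-16,MBON,1,1,,acetylcholine,ap3ap,,SIP SLP LH,False,
MBON-ap3m,MBON-α′3m,MBON-17,MBON,2,2,,acetylcholine,ap3m,,SIP SLP LH,False,
MBON-a2sc,MBON-α2sc,MBON-18,MBON,1,1,,acetylcholine,a2s a2c,,SIP SLP LH,False,
MBON-a2p3p,MBON-α2p3p,MBON-19,MBON,2,2,,acetylcholine,a2p a3p,,SMP,False,input restricted to the α/βp KC layer
MBON-g1g2,MBON-γ1γ2,MBON-20,MBON,1,1,,unknown,g1 g2,,ICL SCL SLP,False,found by photoactivation tracing only
MBON-g4g5,MBON-γ4γ5,MBON-21,MBON,1,1,,unknown,g4 g5,,CRE,False,found by photoactivation tracing only
PAM-g5,PAM-γ5,PAM-01,DAN-PAM,8,21,,dopamine,,g5,SMP CRE,False,
PAM-bp2a,PAM-β′2a,PAM-02,DAN-PAM,6,9,,dopamine,,bp2a,CRE SMP,False,
PAM-b2bp2a,PAM-β2β′2a,PAM-03,DAN-PAM,3,3,more than 3,dopamine,,b2 bp2a,CRE SMP,False,terminals in two compartments
PAM-b2,PAM-β2,PAM-04,DAN-PAM,8,19,,dopamine,,b2,CRE SMP,False,
PAM-bp2p,PAM-β′2p,PAM-05,DAN-PAM,14,17,,dopamine,,bp2p,CRE SMP,False,
PAM-bp2m,PAM-β′2m,PAM-06,DAN-PAM,12,15,,dopamine,,bp2m,CRE SMP,False,
PAM-g4<g1g2,PAM-γ4<γ1γ2,PAM-07,DAN-PAM,13,17,,dopamine,g1 g2,g4,CRE SMP,False,only DAN with dendrites inside the lobes
PAM-g4,PAM-γ4,PAM-08,DAN-PAM,1,13,counted only as a mixture with PAM-g4<g1g2,dopamine,,g4,CRE SMP,False,
PAM-b1ped,PAM-β1ped,PAM-09,DAN-PAM,1,3,,dopamine,,b1 pedc,CRE SMP,False,extends through the pedc toward the calyx
PAM-b1,PAM-β1,PAM-10,DAN-PAM,4,6,,dopamine,,b1,CRE SMP,False,
PAM-a1,PAM-α1,PAM-11,DAN-PAM,6,6,more than 6,dopamine,,a1,CRE SMP SIP,False,
PAM-g3,PAM-γ3,PAM-12,DAN-PAM,9,23,,dopamine,,g3,CRE SMP,False,
PAM-bp1ap,PAM-β′1ap,PAM-13,DAN-PAM,13,14,,dopamine,,bp1ap,CRE SMP,False,
PAM-bp1m,PAM-β′1m,PAM-14,DAN-PAM,1,14,counted only as a mixture with PAM-bp1ap,dopamine,,bp1m,CRE SMP,False,
PPL1-g1pedc,PPL1-γ1pedc,PPL1-01,DAN-PPL1,1,2,,dopamine,,g1 pedc,SMP SIP,False,
PPL1-g1,PPL1-γ1,PPL1-02,DAN-PPL1,1,1,,dopamine,,g1,SMP SIP,False,sparse γ1 innervation
PPL1-g2ap1,PPL1-γ2α′1,PPL1-03,DAN-PPL1,1,1,,dopamine,,g2 ap1,SMP SIP,False,terminals in two compartments
PPL1-ap3,PPL1-α′3,PPL1-04,DAN-PPL1,1,1,,dopamine,,ap3,SMP SIP,False,
PPL1-ap2a2,PPL1-α′2α2,PPL1-05,DAN-PPL1,1,1,,dopamine,,ap2 a2,SMP SIP,False,terminals in two compartments
PPL1-a3,PPL1-α3,PPL1-06,DAN-PPL1,1,1,,dopamine,,a3,SMP SIP,False,
MB-APL,MB-APL,,other-modulatory,1,1,,GABA,,,,False,intrinsic; innervates the whole MB
MB-DPM,MB-DPM,,other-modulatory,1,1,,serotonin,,,,False,intrinsic; innervates the whole MB
MBON-calyx,MBON-calyx,MBON-22,other-modulatory,1,1,atypical output neuron,unknown,,,CRE LH,False,dendrites in calyx and posterior pedunculus
OA-VPM3,OA-VPM3,,other-modulatory,1,1,,octopamine,,,,False,
OA-VPM4,OA-VPM4,,other-modulatory,1,1,,octopamine,,,,False,
SIFamide,SIFamide,,other-modulatory,4,4,,peptide,,,,False,
MB-C1,MB-C1,,other-modulatory,2,2,more than 2,GABA,,,,False,calyx only
CSD,CSD,,other-modulatory,1,1,,serotonin,,,,False,calyx only
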