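name	compartment	role	initial_amount	constant
HGF	extracellular	ligand	0	1
Met	surface	receptor	60000	0
Itg	surface	integrin	100000	0
Met_Itg	surface	complex	0	0
Met_HGF	surface	complex	0	0
Met_Itg_HGF	surface	complex	0	0
pMet	surface	signaling_active	0	0
pMet_Itg	surface	signaling_active	0	0
Met_i	endosomal	receptor	0	0
pMet_i	endosomal	signaling_active	0	0
pMet_Itg_i	endosomal	signaling_active	0	0
Itg_i	endosomal	integrin	0	0
Gab1	cytosolic	signaling_inactive	20000	0
aGab1	cytosolic	signaling_active	0	0
Grb2	cytosolic	signaling_inactive	200000	0
aGrb2	cytosolic	signaling_active	0	0
PI3K	cytosolic	signaling_inactive	50000	0
aPI3K	cytosolic	signaling_active	0	0
PIP2	cytosolic	signaling_inactive	500000	0
PIP3	cytosolic	signaling_active	0	0
Akt	cytosolic	signaling_inactive	150000	0
pAkt	cytosolic	signaling_active	0	0
PDK1	cytosolic	signaling_inactive	100000	0
aPDK1	cytosolic	signaling_active	0	0
SOS	cytosolic	signaling_inactive	30000	0
aSOS	cytosolic	signaling_active	0	0
Ras	cytosolic	signaling_inactive	200000	0
aRas	cytosolic	signaling_active	0	0
Raf	cytosolic	signaling_inactive	40000	0
aRaf	cytosolic	signaling_active	0	0
MEK	cytosolic	signaling_inactive	700000	0
pMEK	cytosolic	signaling_active	0	0
ERK	cytosolic	signaling_inactive	1000000	0
pERK	cytosolic	signaling_active	0	0
RSK	cytosolic	signaling_inactive	100000	0
pRSK	cytosolic	signaling_active	0	0
ppRSK	cytosolic	signaling_active	0	0
PTP	cytosolic	signaling_inactive	50000	1
PP2A	cytosolic	signaling_inactive	100000	1
AXT050	extracellular	drug	0	1
AXT_Itg	surface	complex	0	0
Cabozantinib	extracellular	drug	0	1
Met_Cabo	surface	complex	0	0
Met_Itg_Cabo	surface	complex	0	0
Sorafenib	extracellular	drug	0	1
Rilotumumab	extracellular	drug	0	1
Rilo_HGF	extracellular	complex	0	1
Meti	extracellular	drug	0	1
PDK1i	extracellular	drug	0	1
MEKi	extracellular	drug	0	1
PI3Ki	extracellular	drug	0	1
ERKi	extracellular	drug	0	1
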