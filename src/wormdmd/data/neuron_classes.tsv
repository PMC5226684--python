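# C. elegans neuron class -> member cells (standard hermaphrodite nomenclature).
# Bilateral pairs expand to L/R, ventral-cord motorneuron classes to their
# numbered members, unpaired cells map to themselves.
ALM	ALML,ALMR
AVM	AVM
PLM	PLML,PLMR
AVA	AVAL,AVAR
AVB	AVBL,AVBR
AVD	AVDL,AVDR
AVE	AVEL,AVER
ASH	ASHL,ASHR
AQR	AQR
DVA	DVA
PVC	PVCL,PVCR
PQR	PQR
DA	DA1,DA2,DA3,DA4,DA5,DA6,DA7,DA8,DA9
DB	DB1,DB2,DB3,DB4,DB5,DB6,DB7
DD	DD1,DD2,DD3,DD4,DD5,DD6
VA	VA1,VA2,VA3,VA4,VA5,VA6,VA7,VA8,VA9,VA10,VA11,VA12
VB	VB1,VB2,VB3,VB4,VB5,VB6,VB7,VB8,VB9,VB10,VB11
VD	VD1,VD2,VD3,VD4,VD5,VD6,VD7,VD8,VD9,VD10,VD11,VD12,VD13
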