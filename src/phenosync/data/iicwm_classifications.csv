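bird,insect,al32,al21,iicwm
BS,BM,A,S7,*
BS,CMC,S,A7,-
BS,DA,A,S7,*
BS,ET,S,S4 A3,+
BS,FS,A,S7,*
BS,HD,A,S7,*
BS,LY,A,S7,*
BS,SS,A,S7,-
BS,WE,A,S7,*
BS,GVW,A,S7,-
BS,LW,A,S7,-
BS,MB,A,S7,-
BS,PC,A,S7,*
BS,RA,A,S7,*
BS,RI,A,S7,*
BS,ST,A,S7,-
BS,SMW,A,S7,-
BS,SPW,A,S7,*
GW,BM,A,S7,-
GW,CMC,S,A7,-
GW,DA,A,S7,-
GW,ET,S,A7,+
GW,FS,A,S7,*
GW,HD,A,S7,-
GW,LY,A,S7,*
GW,SS,A,S7,*
GW,WE,A,S7,*
GW,GVW,S,S7,+
GW,LW,S,S7,-
GW,MB,A,S7,-
GW,PC,S,S7,+
GW,RA,S,S7,+
GW,RI,A,S7,-
GW,ST,S,S7,-
GW,SMW,S,S7,+
GW,SPW,S,S7,-
NW,BM,A,S7,*
NW,CMC,S,A7,+
NW,DA,A,S7,-
NW,ET,S,S4 A3,-
NW,FS,A,S7,-
NW,HD,A,S7,-
NW,LY,A,S7,*
NW,SS,A,S7,*
NW,WE,A,S7,*
NW,GVW,A,S7,-
NW,LW,A,S7,*
NW,MB,A,S7,*
NW,PC,A,S7,-
NW,RA,A,S7,*
NW,RI,A,S7,*
NW,ST,A,S7,*
NW,SMW,A,S7,*
NW,SPW,A,S7,*
SW,BM,A,S7,*
SW,CMC,S,A,-
SW,DA,A,S7,-
SW,ET,S,S4 A3,-
SW,FS,A,S7,*
SW,HD,A,S7,*
SW,LY,A,S7,*
SW,SS,A,S7,-
SW,WE,A,S7,-
SW,GVW,S,S7,-
SW,LW,A,S7,+
SW,MB,A,S7,-
SW,PC,S,S7,+
SW,RA,S,S7,-
SW,RI,A,S7,-
SW,ST,S,S7,+
SW,SMW,S,S7,-
SW,SPW,S,S7,+
WW,BM,A,S7,-
WW,CMC,S,A7,-
WW,DA,A,S7,*
WW,ET,S,S4 A3,+
WW,FS,A,S7,-
WW,HD,A,S7,*
WW,LY,A,S7,-
WW,SS,A,S7,*
WW,WE,A,S7,*
WW,GVW,A,S7,-
WW,LW,A,S7,*
WW,MB,A,S7,-
WW,PC,A,S7,*
WW,RA,A,S7,*
WW,RI,A,S7,-
WW,ST,A,S7,-
WW,SMW,A,S7,-
WW,SPW,A,S7,-
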