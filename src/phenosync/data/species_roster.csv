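code,common_name,group,trophic_level
BS,Barn Swallow,bird,3
GW,Greater Whitethroat,bird,3
NW,Northern Wheatear,bird,3
SW,Sedge Warbler,bird,3
WW,Willow Warbler,bird,3
GVW,Green Veined White,butterfly,2
LW,Large White,butterfly,2
MB,Meadow Brown,butterfly,2
PC,Peacock,butterfly,2
RA,Red Admiral,butterfly,2
RI,Ringlet,butterfly,2
ST,Small Tortoiseshell,butterfly,2
SMW,Small White,butterfly,2
SPW,Speckled Wood,butterfly,2
BM,Brimstone Moth,moth,2
CMC,Common Marbled Carpet,moth,2
DA,Dark Arches,moth,2
ET,Early Thorn,moth,2
FS,Flame Shoulder,moth,2
HD,Heart & Dart,moth,2
LY,Large Yellow,moth,2
SS,Small Square,moth,2
WE,White Ermine,moth,2
BW,Bog Woodland,vegetation,1
MBC,Mixed Broadleaf/Conifer Woodland,vegetation,1
MBW,(Mixed) Broadleaf Woodland,vegetation,1
OAH,Oak-Ash-Hazel Woodland,vegetation,1
OBH,Oak-Birch-Holly Woodland,vegetation,1
WOA,Wet Pedunculate Oak-Ash Woodland,vegetation,1
WAA,Wet Willow-Alder-Ash Woodland,vegetation,1
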