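# The six jaw quadrants of the Chaoyangsaurus youngi holotype (IGCAGS V371).
# Count-only fixture (stage = NA): 2 premaxillary teeth (the first left one
# undergoing replacement), 9 functional / 3 replacement maxillary teeth per
# side, 9/3 left dentary and 11/5 right dentary.  Replacement positions
# marked provenance=derived are synthetic except left maxillary tooth 8,
# which is documented in replacement.
specimen_id,taxon,element,side,position,kind,stage,label,skull_length_cm,incomplete,provenance
IGCAGS V371,Chaoyangsaurus youngi,premaxilla,left,1,functional,NA,PM1,13.7,false,text
IGCAGS V371,Chaoyangsaurus youngi,premaxilla,left,1,replacement,NA,rPM1,13.7,false,text
IGCAGS V371,Chaoyangsaurus youngi,premaxilla,right,2,functional,NA,PM2,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,1,functional,NA,M1,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,2,functional,NA,M2,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,2,replacement,NA,rM2,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,3,functional,NA,M3,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,4,functional,NA,M4,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,5,functional,NA,M5,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,5,replacement,NA,rM5,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,6,functional,NA,M6,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,7,functional,NA,M7,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,8,functional,NA,M8,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,8,replacement,NA,rM8,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,left,9,functional,NA,M9,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,1,functional,NA,M1,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,2,functional,NA,M2,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,2,replacement,NA,rM2,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,3,functional,NA,M3,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,4,functional,NA,M4,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,5,functional,NA,M5,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,5,replacement,NA,rM5,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,6,functional,NA,M6,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,7,functional,NA,M7,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,8,functional,NA,M8,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,8,replacement,NA,rM8,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,maxilla,right,9,functional,NA,M9,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,1,functional,NA,D1,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,2,functional,NA,D2,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,2,replacement,NA,rD2,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,3,functional,NA,D3,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,4,functional,NA,D4,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,5,functional,NA,D5,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,5,replacement,NA,rD5,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,6,functional,NA,D6,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,7,functional,NA,D7,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,8,functional,NA,D8,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,8,replacement,NA,rD8,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,left,9,functional,NA,D9,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,1,functional,NA,D1,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,1,replacement,NA,rD1,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,2,functional,NA,D2,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,3,functional,NA,D3,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,3,replacement,NA,rD3,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,4,functional,NA,D4,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,5,functional,NA,D5,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,5,replacement,NA,rD5,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,6,functional,NA,D6,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,7,functional,NA,D7,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,7,replacement,NA,rD7,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,8,functional,NA,D8,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,9,functional,NA,D9,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,9,replacement,NA,rD9,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,10,functional,NA,D10,13.7,false,derived
IGCAGS V371,Chaoyangsaurus youngi,dentary,right,11,functional,NA,D11,13.7,false,derived
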