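# Right maxilla of IVPP V18638 (Yinlong downsi), 13 alveoli: 10 functional
# teeth, 3 empty alveoli, 3 replacement teeth (rM1, rM2, rM10).
# Stage values marked provenance=derived are reconstructions consistent with
# the published run memberships (M1-M3, M5-M6, M8-rM10, M10-M11 descending;
# rM1, rM2, M13 exceptions); per-tooth stages were published only graphically.
# Open pulp cavities of M3 and M9 (-> F1) are stated in the text.
specimen_id,taxon,element,side,position,kind,stage,label,skull_length_cm,incomplete,provenance
IVPP V18638,Yinlong downsi,maxilla,right,1,functional,F4,M1,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,1,replacement,R1,rM1,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,2,functional,F3,M2,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,2,replacement,R1,rM2,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,3,functional,F1,M3,13.4,true,text
IVPP V18638,Yinlong downsi,maxilla,right,4,empty_alveolus,NA,,13.4,true,text
IVPP V18638,Yinlong downsi,maxilla,right,5,functional,F3,M5,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,6,functional,F2,M6,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,7,empty_alveolus,NA,,13.4,true,text
IVPP V18638,Yinlong downsi,maxilla,right,8,functional,F4,M8,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,9,functional,F1,M9,13.4,true,text
IVPP V18638,Yinlong downsi,maxilla,right,10,functional,F4,M10,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,10,replacement,R3,rM10,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,11,functional,F1,M11,13.4,true,derived
IVPP V18638,Yinlong downsi,maxilla,right,12,empty_alveolus,NA,,13.4,true,text
IVPP V18638,Yinlong downsi,maxilla,right,13,functional,F1,M13,13.4,true,derived
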