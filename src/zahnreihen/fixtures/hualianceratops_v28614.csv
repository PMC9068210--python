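# Left dentary of Hualianceratops wucaiwanensis IVPP V28614: 10 functional
# dentary teeth (the first broken, root only) and 5 replacement teeth exposed
# lingually.  Count-only fixture; replacement positions are synthetic
# (provenance=derived).
specimen_id,taxon,element,side,position,kind,stage,label,skull_length_cm,incomplete,provenance
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,1,functional,NA,D1,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,2,functional,NA,D2,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,2,replacement,NA,rD2,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,3,functional,NA,D3,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,4,functional,NA,D4,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,4,replacement,NA,rD4,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,5,functional,NA,D5,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,6,functional,NA,D6,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,6,replacement,NA,rD6,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,7,functional,NA,D7,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,8,functional,NA,D8,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,8,replacement,NA,rD8,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,9,functional,NA,D9,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,10,functional,NA,D10,,false,derived
IVPP V28614,Hualianceratops wucaiwanensis,dentary,left,10,replacement,NA,rD10,,false,derived
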