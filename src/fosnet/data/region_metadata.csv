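region,name,anatomical_group,cholinergic_group,subsystem
MA,Magnocellular nucleus,pallidum,Ch4,BFCS
NDB,Diagonal band nucleus,pallidum,Ch2,BFCS
SI,Substantia innominata,pallidum,Ch4,BFCS
MS,Medial septal nucleus,pallidum,Ch1,BCS
PPN,Pedunculopontine nucleus,midbrain,Ch5,BCS
MH,Medial habenula,thalamus,Ch7,BCS
LH,Lateral habenula,thalamus,Ch7,BCS
ACA,Anterior cingulate area,cortical plate,,
ILA,Infralimbic area,cortical plate,,
PL,Prelimbic area,cortical plate,,
DP,Dorsal peduncular area,cortical plate,,
GU,Gustatory areas,cortical plate,,
VISpl,Posterolateral visual area,cortical plate,,
FRP,Frontal pole cerebral cortex,cortical plate,,
CP,Caudoputamen,striatum,,
ACB,Nucleus accumbens,striatum,,
FS,Fundus of striatum,striatum,,
CEA,Central amygdalar nucleus,striatum,,
BLA,Basolateral amygdalar nucleus,cortical subplate,,
BST,Bed nuclei of the stria terminalis,pallidum,,
PVH,Paraventricular hypothalamic nucleus,hypothalamus,,
PS,Parastrial nucleus,hypothalamus,,
VTA,Ventral tegmental area,midbrain,,
IPN,Interpeduncular nucleus,midbrain,,
CUN,Cuneiform nucleus,midbrain,,
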