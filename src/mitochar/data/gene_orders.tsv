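# Named mitochondrial gene orders over the 37-gene vocabulary plus CR, as
# signed circular token strings (leading "-" = light strand / opposite
# transcriptional orientation; tokens read left to right around the circle,
# anchored at cox1). Transcribed from published linear gene-arrangement maps;
# any transcription ambiguity is isolated to this file.
#
# ancestral_decapoda: the decapod / pancrustacean ground pattern.
# ancestral_caridea: identical to the decapod ground pattern at token level.
# ensirostris: Exhippolysmata ensirostris (trnL2 shifted downstream of cox2).
# alpheidae: Alpheus distinguendus group (trnE moved next to trnP, inverted).
# alpheus_lobidens: alpheidae pattern plus a second trnQ downstream of nad4l.
Name	Order
ancestral_decapoda	cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4l,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
ancestral_caridea	cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4l,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
ensirostris	cox1,cox2,trnL2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,trnE,-trnF,-nad5,-trnH,-nad4,-nad4l,trnT,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
alpheidae	cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,-trnF,-nad5,-trnH,-nad4,-nad4l,trnT,-trnE,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
alpheus_lobidens	cox1,trnL2,cox2,trnK,trnD,atp8,atp6,cox3,trnG,nad3,trnA,trnR,trnN,trnS1,-trnF,-nad5,-trnH,-nad4,-nad4l,-trnQ#2,trnT,-trnE,-trnP,nad6,cob,trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,CR,trnI,-trnQ,trnM,nad2,trnW,-trnC,-trnY
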