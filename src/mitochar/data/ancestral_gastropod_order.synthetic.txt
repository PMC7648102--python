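# SYNTHETIC stand-in for a hypothetical ancestral gastropod gene order.
# This editable configuration file is patterned on the conserved molluscan /
# vetigastropod-like arrangement; it is NOT a transcription of any published
# ancestral-state reconstruction.  Replace the line below with the reference
# order you want rearrangement reports computed against (comma-separated
# signed gene symbols, circular; a leading '-' marks the minus strand).
cox1,cox2,-trnD,atp8,atp6,-trnF,-nad5,-trnH,-nad4,-nad4l,-trnT,-trnS2,cytb,nad6,trnP,-nad1,-trnL1,-trnL2,rrnL,-trnV,-rrnS,trnM,trnC,-trnQ,trnG,trnE,-trnS1,nad3,trnR,-trnN,-nad2,trnI,-cox3,-trnK,-trnA,-trnY,-trnW
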