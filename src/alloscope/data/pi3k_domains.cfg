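# PI3Kalpha domain map (crystal/author numbering).
# Chain A = p110alpha (catalytic subunit), chain B = p85alpha (regulatory subunit).
# Domain spans follow the community/domain assignment used for the
# dynamical-network partitioning of the heterodimer; they are recorded as
# stated there and are not reconciled against UniProt domain boundaries.
ABD = A:1-108
RBD = A:190-300
C2 = A:335-478
helical = A:526-643
kinase = A:699-1067
kinase_nlobe = A:699-808
kinase_clobe = A:809-1067
nSH2 = B:322-428
iSH2 = B:429-600
activation_loop = A:933-958
helix_339_347 = B:339-347
helix_400_410 = B:400-410
ialpha3 = B:587-598
residue_545 = A:545
residue_542 = A:542
residue_358 = B:358
residue_340 = B:340
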