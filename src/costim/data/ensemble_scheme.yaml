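# Default variant scheme for the model ensemble.
#
# Three families, all enumerated against the peptide-level base model:
#   1. the four combinations of the two proposed crosstalk mechanisms
#      (restricting Ste20's crosstalk mediation to Ste20_T511; the
#      double-negative Gpd1--Hog1 feedback loop);
#   2. removal of interaction groups classified as No Effect upon NaCl
#      stimulation, one group per variant (the Hog1/Ptp2 group removes the
#      edges from both Hog1 phospho-forms to Ptp2_S258);
#   3. removal of fifteen documented single interactions, one at a time.
# Together with deduplication this enumerates 23 distinct models.
mechanism_combos:
  - {restrict_ste20_to_T511: false, add_gpd1_hog1_loop: false}
  - {restrict_ste20_to_T511: true, add_gpd1_hog1_loop: false}
  - {restrict_ste20_to_T511: false, add_gpd1_hog1_loop: true}
  - {restrict_ste20_to_T511: true, add_gpd1_hog1_loop: true}
no_effect_groups:
  sho1_ste20_T573:
    - [Sho1, 1, Ste20_T573]
  ssk2_pbs2_S68:
    - [Ssk2_S53_S57, 1, Pbs2_S68]
  complex_pbs2_S269:
    - [Ste11_Ste50_complex, 1, Pbs2_S269]
  hog1_ptp2_S258:
    - [Hog1_T174_Y176, 1, Ptp2_S258]
    - [Hog1_Y176, 1, Ptp2_S258]
single_removals:
  - [Ptp2_S258, -1, Hog1_T174_Y176]
  - [Ptp2_S258, -1, Hog1_Y176]
  - [Ptc1, -1, Hog1_T174_Y176]
  - [Ptc1, -1, Hog1_Y176]
  - [Pbs2_S68, 1, Hog1_T174_Y176]
  - [Pbs2_S248, 1, Hog1_T174_Y176]
  - [Pbs2_S269, 1, Hog1_T174_Y176]
  - [Ssk1_S673, 1, Ssk2_S53_S57]
  - [Nbp2_S196, 1, Ptc1]
  - [Ypk1_S644_S653, -1, Gpd1_S24_S27]
  - [Bit61_S139_S144, 1, Ypk1_S644_S653]
  - [Hog1_T174_Y176, 1, Hot1_S153]
  - [Hog1_T174_Y176, -1, Ste5]
  - [Fus3_T180_Y182, 1, Far1_S114]
  - [Ste7, 1, Fus3_T180_Y182]
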