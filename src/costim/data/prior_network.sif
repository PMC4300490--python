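# Protein-level prior-knowledge network for the yeast HOG and pheromone
# MAPK pathways (synthetic transcription: assembled from the canonical
# pathway literature to serve as the modeling prior; see docs/methods.md).
# Stimuli: NaCl (hyper-osmotic shock), Pheromone (alpha-factor).
# Sln1 branch
NaCl 1 Sln1
Sln1 1 Ypd1
Ypd1 -1 Ssk1
Ssk1 1 Ssk2
Ssk1 1 Ssk22
Ssk2 1 Pbs2
Ssk22 1 Pbs2
# Sho1 branch and shared components
NaCl 1 Sho1
NaCl 1 Msb2
Msb2 1 Sho1
Sho1 1 Ste20
Cdc42 1 Ste20
Ste20 1 Ste11
Ste20 1 Ste11_Ste50_complex
Ste11 1 Ste11_Ste50_complex
Ste50 1 Ste11_Ste50_complex
Ste11_Ste50_complex 1 Pbs2
Pbs2 1 Hog1
# Hog1 outputs and feedback
Hog1 1 Hot1
Hog1 1 Sko1
Hog1 1 Rck2
Hog1 -1 Fps1
Hog1 1 Ptp2
Ptp2 -1 Hog1
Ptc1 -1 Hog1
Nbp2 1 Ptc1
Pbs2 1 Nbp2
Hog1 -1 Ste5
# Pheromone pathway
Pheromone 1 Ste2
Ste2 1 Ste4
Ste4 1 Cdc42
Ste4 1 Ste5
Ste5 1 Ste7
Ste7 1 Fus3
Fus3 1 Dig1
Fus3 1 Dig2
Fus3 1 Ste12
Fus3 1 Far1
Fus3 1 Sic1
Dig1 -1 Ste12
Dig2 -1 Ste12
Ste12 1 Tec1
# TORC2 arm regulating Gpd1
NaCl -1 Ypk1
NaCl -1 Bit61
Bit61 1 Ypk1
Ypk1 -1 Gpd1
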