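{
 "outdir": "run",
 "seed": 0,
 "n_proteins": 30,
 "protein_length": 200,
 "n_interfaces": 40,
 "positions_per_interface": 6,
 "partner_class_mix": {
  "protein": 0.5,
  "chemical": 0.4,
  "dna_rna": 0.1
 },
 "n_samples_per_type": 75,
 "cancer_types": [
  [
   "lung",
   "adenocarcinoma"
  ],
  [
   "lung",
   "squamous_cell_carcinoma"
  ],
  [
   "breast",
   "ductal_carcinoma"
  ],
  [
   "large_intestine",
   "adenocarcinoma"
  ]
 ],
 "background_rate": 3.0,
 "planted_drivers": [
  [
   "IF0001",
   0.3,
   "disabling"
  ],
  [
   "IF0002",
   0.3,
   "enabling"
  ],
  [
   "IF0003",
   0.25,
   "disabling"
  ]
 ],
 "exclusivity_pairs": [
  [
   "IF0001",
   "IF0002"
  ]
 ],
 "q_max": 0.01,
 "min_samples": 20,
 "replicates": 5,
 "depth_cutoff": 0.9,
 "cluster_metric": "correlation",
 "exclusivity_q": 0.1,
 "mutex_min_pan": 20,
 "mutex_min_per_cancer": 10,
 "differential_min_per_type": 5,
 "baseline_hazard": 0.01,
 "group_hazards": {
  "IF0001": 2.0,
  "IF0002": 1.0,
  "none": 1.0
 },
 "censoring_fraction": 0.2,
 "covariate_effects": {
  "age": 0.0,
  "sex": 0.0
 }
}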