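{
 "seed": 7,
 "outdir": "scratch/demo_run",
 "n_proteins": 4,
 "n_conditions": 20,
 "n_replicates": 5,
 "dynamic_fraction": 0.06,
 "noise_sd_oxidation": 2.0,
 "threshold": 10.0,
 "gap_open": 10.0,
 "gap_extend": 1.0,
 "engagement_doses": [5.0, 10.0, 20.0, 40.0],
 "engagement_n_sites": 25,
 "engagement_noise_cv": 0.1,
 "engagement_replicates": 3,
 "r_threshold": 2.0,
 "min_pair_fraction": 0.75,
 "in_domain_fraction": 0.95,
 "doseresponse_points": 10,
 "doseresponse_cv": 0.02,
 "doseresponse_replicates": 4
}
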