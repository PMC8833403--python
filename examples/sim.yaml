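n_mz: 500
n_dz: 700
sigma2_ap: 0.101
sigma2_ab: 0.614
sigma2_e: 0.285
prevalence: 0.27
incomplete_rate: 0.3
seed: 42
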