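# A light-weight population for quick runs: 4 sites, 3 units each,
# 30 trials per block. Omit keys to fall back to the study-condition defaults.
n_sites: 4
n_units: 3
trials_per_block: 30
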