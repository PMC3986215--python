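# Fragile single-path module: expected label "non_tolerant"
preset: non_tolerant_like
base_seed: 1
replicates: 10
folds: 5
method: netscore
critical_threshold: 50
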