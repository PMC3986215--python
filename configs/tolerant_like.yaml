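# Redundantly wired disease module: expected label "tolerant"
preset: tolerant_like
base_seed: 1
replicates: 10
folds: 5
method: netscore
critical_threshold: 50
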