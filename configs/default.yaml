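# Default ephespec run configuration.
# Rates are per incipient lineage per Myr; times in Myr.
# lambda_i / lambda_f ~ 33: incipient lineages arise 30-40x faster than
# full species form, the regime estimated for bird subspeciation.
model: ephemeral
lambda_i: 1.0
mu_i: 0.5
lambda_f: 0.03
t_max: 10.0
max_lineages: 50000
seed: 0
replicates: 10
condition_on_survival: true
max_tries: 1000
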