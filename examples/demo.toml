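# Demo pipeline configuration: simulate -> analyze -> report.
# Run with: phrasal run --config examples/demo.toml --out runs/demo
seed = 1
stages = ["synth", "tfr", "connectivity", "pac", "binding", "cluster"]

[synth]
n_trials = 20
n_channels = 3
fs = 256.0
phase_lock_strength = 0.6   # planted intertrial phase coherence
alpha_power_change = -3.0   # dB post-onset alpha change
pac_modulation = 0.6        # theta-gamma coupling depth
noise_sd = 1.0

[tfr]
n_freqs = 24                # wavelet bank size for the demo run

[pac]
n_perm = 200
n_channels = 1

[binding]
n_pairs = 20
noise_sd = 0.2
power_coupling = false

[cluster]
n_perm = 200
n_subjects = 10
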