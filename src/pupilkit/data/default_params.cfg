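# pupilkit simulator default parameter table (v1)
# One key per line; values parsed as Python literals.
n_participants: 14
fs: 250.0
sessions: 3
trials_per_duration: 10
durations: (3.0, 6.0, 9.0)
iti_bounds: (5.0, 8.0)
lead_in: 5.0
lead_out: 4.0
baseline_diameter: 4.7
baseline_sd: 0.5
fast_amplitude: 0.6
fast_latency: 0.6
fast_rise: 0.88
fast_plateau_frac: 0.6
fast_decay_tau: 0.8
slow_amplitude: 0.25
slow_latency: 1.48
slow_tau: 1.5
offset_tau: 1.0
amplitude_cv: 0.2
latency_sd: 0.08
blink_rate: 0.15
blink_duration: (0.10, 0.25)
blink_edge: 0.008
blink_collapse: 0.02
hippus_amplitude: 0.05
hippus_freq: 0.2
noise_sd_area: 0.3
rt_mean: 0.56
rt_sd: 0.09
press_interval: 0.3
rng_seed: 0
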