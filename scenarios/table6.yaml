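# Type I error / power grid with a treatment-responsive reference gene
rhos: [0.0, 0.5, 0.9]
shapes: [gaussian, right_skewed, left_skewed]
n_per_group: 5
target_effect: 2.0
reference_effect: 1.0
alpha: 0.05
n_reps: 10000
seed: 20250213
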