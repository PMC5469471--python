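# Demo pipeline configuration: a 1000-meadow synthetic landscape with
# 22 stock meadows and disturbance injected above 230 max stock nights/ha.
seed: 7
outdir: meadowpack_out
n_meadows: 1000
n_stock: 22
bare_dry_effect: 50.0
use_threshold: 230.0
wet_dispersion_factor: 3.0
breaks: [-0.5, 0.5]
window_width: 0.25
b_reps: 1000
top_k_per_park: 20
top_n_candidates: 3
min_split: 5
min_leaf: 2
prune_frac: 0.10
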