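# Small synthetic demonstration run: a 200 x 250 m stand of three
# clustered species tied to a land-use mosaic, analysed end to end.

[run]
seed = 11
outdir = "runs/demo"

[synthetic]
n_species = 3
total_stems = 1500
window_width = 200.0
window_height = 250.0

[spatial]
top_k_species = 2
r_max_pcf = 50.0
r_max_mark = 80.0
r_step = 2.0
bandwidth = 5.0
nsim = 199
rank = 5

[importance]
radius = 10.0
cell_size = 20.0
n_iter = 50
subsample = 0.632
alpha = 0.05
min_node = 20
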