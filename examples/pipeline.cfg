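# Desk-scale end-to-end run: 60 phantoms, 64x64, full grid evaluation.
# All randomness derives from [run] seed.

[run]
seed = 0
outdir = runs/demo

[phantom]
preset = easy
n_benign = 30
n_malignant = 30

[split]
n_train = 40
n_test = 20
stratify = true

[model]
preset = desk
latent_keep = 4

[train]
epochs = 30
batch_size = 8
lr_start = 3e-3
lr_end = 1e-4

[radiomics]
masks = predicted
n_gray_levels = 32

[reduce]
n_components = 12
k_neighbors = 10
transductive = false

[classify]
n_boot = 1000
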