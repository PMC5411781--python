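# Default pcfkit run configuration (all values shown are the defaults;
# any key may be omitted). Unknown keys are rejected.

seed: 42
mode: simulate            # simulate | real-input

# ancestor genome and rearrangement plan
n_chromosomes: 5
chrom_bp: 4000000
mshsb_per_chrom: 1
mshsb_bp: 1800000
n_inversions: 10
n_fusions: 3
n_fissions: 2

# scaffold shredding and mate-pair coverage
mean_scaffold_bp: 1000000
chimera_rate: 0.1
n_pairs: 60000
insert_mean: 3000.0
insert_sd: 300.0
p_chim_zero: 0.9          # probability a chimeric joint has zero spanning pairs

# feature tracks
cne_density_mshsb: 0.11
cne_density_background: 0.02
desert_halfwidth_bp: 50000

# probes
probe_spacing_bp: 500000
probe_position_noise_sd: 0.0

# synteny / PCF construction
resolution: 150000
min_block_bp: 5000
block_bp: 40000
edge_erosion_bp: 5000
threshold_c: calibrate    # "calibrate" or a non-negative integer
w_ref: 1.0
w_out: 1.0
w_read: 1.0
join_min: 2.0
coverage_mode: min        # min | midpoint

# statistics
window_bp: 1000
te_window_bp: 10000
alpha: 0.05
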