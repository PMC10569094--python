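# Example run configuration: a small slit-confined melt.
# H_over_a values from the physical-parameter table map onto integer
# lattice gaps (2.12 -> 3 grid units); omit H_over_a for bulk.
N = 80
M = 19
rho_site = 0.8333333333333334
kappa_bend = 2.0
H_over_a = 2.12
crossing_rate = 1e-4
steps = 20000000
snapshot_stride = 2000000
seed = 1
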