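# Zero-variance test profile: every sampler becomes deterministic.
# Daughter diameter = parent * 2^(-1/3) (perfectly symmetric Murray split),
# vessel length = 7.5 * diameter, arteriole diameter fixed at 19.25 um.
name: degenerate
ddp_mean_coeffs: [0.0, 0.7937005259840998]
ddp_sd_coeffs: [0.0]
vlvd_mean_coeffs: [0.0, 7.5]
vlvd_sd_coeffs: [0.0]
aa_spacing_rate: 0.02
aa_diam_mean: 19.25
aa_diam_sd: 0.0
valid_diameter_range: [1.0, 1000.0]
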