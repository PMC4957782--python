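# Default rat-kidney morphometric profile.
#
# The published fits behind this profile exist only as figures (cubic mean /
# linear SD for daughter-vs-parent diameter from micro-CT morphometry of the
# renal arterial tree; linear mean/SD for length-vs-diameter fitted over
# 20-100 um; exponential inter-arteriole spacing measured on optically
# cleared tissue; Gaussian afferent-arteriole diameters).  The coefficients
# below are approximate digitizations of those curves, calibrated by
# simulation so that whole-kidney trees grown from a 530 um renal artery
# down to a 22 um stop diameter reproduce realistic afferent-arteriole
# statistics (~20k arterioles of ~19.3 um mean diameter for the
# terminal-only ABT, ~31k arterioles for the kidney-specific KSABT).
# Murray's law ties arteriole count to arteriole diameter (the terminal
# diameter cubes must sum to the root diameter cube), which fixes most of
# the freedom here; see docs/methods.md.
name: default
# mean daughter diameter (um) vs parent diameter: cubic, ratio ~0.80 for
# small vessels rising to ~0.83 at the renal artery (mild asymmetry of the
# main continuation branch)
ddp_mean_coeffs: [0.2305811404441749, 0.7860036706290152, 0.00012497822688228375, -8.073047216867343e-08]
# SD of daughter diameter (um) vs parent diameter: linear
ddp_sd_coeffs: [0.2, 0.025]
# vessel length (um) vs diameter: linear mean and SD
vlvd_mean_coeffs: [0.0, 12.0]
vlvd_sd_coeffs: [0.0, 3.6]
# vessel length ~12x diameter (consistent with a ~300 um feeding vessel of
# ~25 um diameter), broad scatter
# exponential rate (1/um) of spacing between neighboring arteriole origins;
# mean spacing ~67 um, high density of (near-)doublets, >300 um gaps rare
aa_spacing_rate: 0.015
# side-branching afferent-arteriole diameter (um), Gaussian
aa_diam_mean: 16.4
aa_diam_sd: 1.8
valid_diameter_range: [20.0, 530.0]
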