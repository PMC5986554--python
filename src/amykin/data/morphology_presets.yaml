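# Frozen particle-mixture presets emulating the AFM morphometry of
# amyloid-beta(1-42) aggregates under different membrane conditions.
#
# Each preset is a mixture of synthetic species.  Lengths are log-normal
# (median nm, sigma of ln-length); heights are normal truncated at 0
# (mean nm, SD nm).  The weights were chosen so that the analytic
# probability mass of each mixture inside the reported length/height bins
# matches the published percentages:
#   alone_12h  : protofibril-dominated (50-250 nm x 1-4 nm ~ 82.5%)
#   alone_24h  : fibril-dominated      (200-1000 nm x 2-6 nm ~ 80%)
#   dopc_24h   : fibril-length, protofibril-height (1-4 nm ~ 77%)
#   chol_12h   : fibrils appear early; fibril-dominated
#   chol_24h   : fibril-dominated, as chol_12h
#   7keto_24h  : protofibril-dominated (50-250 nm x 1-4 nm ~ 85%)
# These are documented emulation constants, not fitted values.
schema_version: 1
species_library:
  protofibril:
    length_median_nm: 120.0
    length_sigma_log: 0.28
    height_mean_nm: 2.3
    height_sd_nm: 0.55
  fibril:
    length_median_nm: 430.0
    length_sigma_log: 0.45
    height_mean_nm: 3.6
    height_sd_nm: 0.9
  thin_fibril:
    length_median_nm: 430.0
    length_sigma_log: 0.45
    height_mean_nm: 2.3
    height_sd_nm: 0.65
presets:
  alone_12h:
    protofibril: 0.83
    fibril: 0.17
  alone_24h:
    protofibril: 0.10
    fibril: 0.90
  dopc_24h:
    thin_fibril: 0.33
    fibril: 0.67
  chol_12h:
    protofibril: 0.08
    fibril: 0.92
  chol_24h:
    protofibril: 0.08
    fibril: 0.92
  7keto_24h:
    protofibril: 0.88
    fibril: 0.12
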