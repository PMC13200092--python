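# Combined-indicator (cB-12) constants — versioned configuration.
#
# The 3-marker form implemented by b12status is
#   3cB-12 = e_b*log10(B-12) + e_m*log10(MMA) + e_t*log10(tHcy)
#            + offset - age_factor(age),   age_factor = sum_k c_k (age/100)^k
#
# These default numeric values are a documented transcription choice for the
# modified combined indicator with holoTC unavailable: holoTC is dropped from
# the numerator and the offset recentres the score so a B-12-adequate adult
# population sits near +0.5 with a small (~2-5%) tail at or below the
# inadequate boundary of -0.5.  They are suitable for the synthetic-survey
# workflow shipped with the package.  For analyses of real data, replace this
# file with constants verified against the combined-indicator source
# publications (Fedosov et al.) and keep the version string unique: the
# constants are echoed into every results manifest.
version: b12status-default-1
citation: >-
  Combined indicator of vitamin B-12 status (cB-12), modified 3-marker form
  after Fedosov et al. (Clin Chem Lab Med 2015;53:1215-25); numeric values
  are the package's documented transcription choice, see docs/methods.md.
three_marker_exponents:
  b12: 1.0
  mma: -1.0
  thcy: -1.0
three_marker_offset: 0.95
age_factor_coeffs: [0.0, 0.0, 0.5]
status_cutoff: -0.5
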