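"""Shared numerical constants.

Standard-normal quantiles are fixed at four decimal places, the convention in
the occupational-exposure literature, rather than recomputed at full
precision, so that percentile formulas such as ``gm * gsd ** Z95`` reproduce
published numbers digit for digit.
"""

#: Standard normal 90th-percentile quantile, used for the P90 comparator.
Z90 = 1.2816

#: Standard normal 95th-percentile quantile, used for the P95 criterion.
Z95 = 1.6449

#: South African occupational exposure limit for respirable coal dust,
#: mg/m3 as an 8-hour time-weighted average.
DEFAULT_OEL = 2.0
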