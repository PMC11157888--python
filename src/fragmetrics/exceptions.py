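"""Exceptions shared across the package."""


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined for the given input.

    Raised instead of silently returning NaN, e.g. for a constant hourly
    series (zero total variance makes IS and IV undefined) or a maximum
    likelihood transition probability whose denominator is zero because the
    state was never observed, or was observed only in a single fully
    censored bout.
    """
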