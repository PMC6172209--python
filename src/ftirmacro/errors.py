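"""Exception taxonomy.

All errors raised for bad *inputs* derive from :class:`ValueError` so that
callers can catch them uniformly; more specific subclasses distinguish the
degenerate-data cases that the analysis stages surface.
"""


class GridMismatchError(ValueError):
    """Two spectra do not share the same wavenumber grid."""


class DegenerateSpectrumError(ValueError):
    """A spectrum is flat/zero where the operation needs structure."""


class DegenerateReferenceError(DegenerateSpectrumError):
    """The background reference carries no signal in the fit window."""


class NormalizationError(ValueError):
    """Percent-of-untreated normalization cannot be carried out."""


class UndefinedRatioError(ValueError):
    """A ratio statistic has a zero denominator."""


class ConfigError(ValueError):
    """Pipeline configuration failed validation."""
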