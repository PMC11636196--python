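"""Structured exceptions shared across the package."""


class GbmRiskError(ValueError):
    """Base class for all validation and modelling errors."""


class ShareMatrixError(GbmRiskError):
    """Malformed share matrix (row sums, bounds, label mismatch).

    Carries the offending row/column labels when known so callers can
    report exactly which entry of a scenario file is broken.
    """

    def __init__(self, message, *, rows=None, cols=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []
        self.cols = list(cols) if cols is not None else []


class GraphError(GbmRiskError):
    """Invalid compartment graph (cycles, dangling sinks, missing priors)."""


class UnitError(GbmRiskError):
    """Incompatible or unknown concentration units."""


class HazardDataError(GbmRiskError):
    """Invalid or insufficient toxicity records."""
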