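"""Risk characterization: RCR = PEC / PNEC distributions.

An RCR at or above 1 flags potential environmental risk; the headline
statistics are the mean, the interquartile range, the exceedance
probability at 1, and how many orders of magnitude the mean lies below
the trigger value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GbmRiskError, UnitError
from .exposure import ConcentrationDistribution
from .hazard import SSDResult
from . import units


@dataclass
class RCRDistribution:
    """Dimensionless PEC/PNEC samples with the unit audit trail."""

    samples: np.ndarray
    pec_unit: str
    pnec_unit: str

    def __post_init__(self):
        self.samples = np.atleast_1d(np.asarray(self.samples, dtype=float))
        if np.any(self.samples < 0):
            raise GbmRiskError("RCR samples must be non-negative")

    def mean(self) -> float:
        return float(self.samples.mean())

    def summary(self) -> pd.Series:
        q25, q75 = np.percentile(self.samples, [25, 75])
        m = self.mean()
        return pd.Series({
            "mean": m, "q25": float(q25), "q75": float(q75),
            "p_exceed_1": exceedance_probability(self),
            "orders_below_one": orders_below_one(m) if m > 0 else math.inf,
        })


def rcr_distribution(pec: ConcentrationDistribution,
                     pnec: "SSDResult | float | ConcentrationDistribution",
                     seed=None, pnec_unit: str = "mg/L") -> RCRDistribution:
    """Divide the PEC distribution by a PNEC distribution or point value.

    Distribution / distribution: both are independently resampled with
    replacement (seeded) to a common sample count — the exposure and
    hazard Monte-Carlo chains share no randomness, so pairing would be
    arbitrary.  Distribution / point: element-wise division.  Units are
    reconciled before dividing; zero-PEC samples give zero RCR.
    """
    if isinstance(pnec, SSDResult):
        pnec_samples, p_unit = np.asarray(pnec.hc5_samples, float), pnec.unit
    elif isinstance(pnec, ConcentrationDistribution):
        pnec_samples, p_unit = pnec.samples, pnec.unit
    else:
        pnec_samples, p_unit = np.atleast_1d(float(pnec)), pnec_unit
    if units.family(pec.unit) != units.family(p_unit):
        raise UnitError(f"PEC unit {pec.unit} incompatible with PNEC unit {p_unit}")
    factor = units.conversion_factor(pec.unit, p_unit)
    pec_samples = pec.samples * factor
    if np.any(pnec_samples <= 0):
        raise GbmRiskError("PNEC samples must be strictly positive")
    if pnec_samples.size == 1:
        ratios = pec_samples / pnec_samples[0]
    else:
        n = max(pec_samples.size, pnec_samples.size)
        rng = np.random.default_rng(seed)
        pe = pec_samples[rng.integers(0, pec_samples.size, n)]
        pn = pnec_samples[rng.integers(0, pnec_samples.size, n)]
        ratios = pe / pn
    return RCRDistribution(ratios, pec.unit, p_unit)


def orders_below_one(mean_rcr: float) -> int:
    """floor(-log10(mean RCR)): whole orders of magnitude below the trigger.

    A mean above 1 returns 0 with a warning (the ratio is not below the
    trigger at all); non-positive means are an error.
    """
    if mean_rcr <= 0:
        raise GbmRiskError("mean RCR must be positive")
    if mean_rcr > 1:
        warnings.warn("mean RCR exceeds 1; no orders below the trigger value",
                      stacklevel=2)
        return 0
    # epsilon guards against 1e-5 landing at 4.9999... in floating point
    return int(math.floor(-math.log10(mean_rcr) + 1e-9))


def exceedance_probability(rcr: RCRDistribution, threshold: float = 1.0) -> float:
    """Empirical fraction of RCR samples above the threshold."""
    if rcr.samples.size == 0:
        raise GbmRiskError("empty RCR distribution")
    return float(np.mean(rcr.samples > threshold))
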