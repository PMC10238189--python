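"""Absolute quantification: positive wells -> molecules -> copies per mL plasma.

Digital PCR counts positive partitions, not molecules: a well holding two
molecules still lights up once.  Under uniform Poisson loading the mean
occupancy is recoverable from the positive fraction as
``lambda = -ln(1 - k/N)``, and the molecule estimate is ``lambda * N``
(the standard dPCR multi-occupancy correction).  Copies per mL of plasma
additionally divide by the plasma-equivalent volume assayed and by the
fraction of master mix retained in wells.

Standard-curve evaluation follows the dilution-series conventions: an OLS
fit of detected vs expected over the nonzero ladder points (linear axes),
LOD = lowest nominal detected in at least one replicate, LOQ = lowest
nominal detected in all replicates, analytical specificity =
LOQ / background copies x 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SaturationError, UndefinedCurveError

__all__ = [
    "QuantResult",
    "CurveMetrics",
    "poisson_correct",
    "copies_per_ml",
    "quantify_counts",
    "standard_curve_metrics",
]


def poisson_correct(positive_count: int, n_wells: int) -> tuple[float, float]:
    """Multi-occupancy correction: (lambda_hat, corrected_copies).

    ``lambda_hat = -ln(1 - k/N)`` molecules per well;
    ``corrected_copies = lambda_hat * N`` molecules in the module.
    Monotone increasing in the positive count and never below it.
    """
    if n_wells < 1:
        raise DomainError("n_wells must be >= 1")
    if positive_count < 0 or positive_count > n_wells:
        raise DomainError("positive_count must be in [0, n_wells]")
    if positive_count == n_wells:
        raise SaturationError(
            "all wells positive: occupancy estimate undefined (saturation)"
        )
    lam = -np.log1p(-positive_count / n_wells)
    return float(lam), float(lam * n_wells)


def copies_per_ml(
    corrected_copies: float,
    plasma_equiv_volume_ml: float,
    retention_fraction: float = 1.0,
) -> float:
    """Copies per mL of plasma: corrected copies / (volume x retention)."""
    if plasma_equiv_volume_ml <= 0:
        raise DomainError("plasma_equiv_volume_ml must be > 0")
    if not (0.0 < retention_fraction <= 1.0):
        raise DomainError("retention_fraction must be in (0, 1]")
    if corrected_copies < 0:
        raise DomainError("corrected_copies must be >= 0")
    return float(corrected_copies / (plasma_equiv_volume_ml * retention_fraction))


@dataclass
class QuantResult:
    """Absolute quantification of one channel of one module."""

    channel: str
    positive_count: int
    lambda_hat: float
    corrected_copies: float
    copies_per_ml: float
    plasma_equiv_volume_ml: float
    retention_fraction_used: float


def quantify_counts(
    positive_counts: dict[str, int],
    n_wells: int,
    plasma_equiv_volume_ml: float = 0.1,
    retention_fraction: float = 0.5,
) -> pd.DataFrame:
    """Quantify every channel's positive count; one row per channel.

    Columns keep the raw count, the Poisson-corrected molecule estimate and
    the retention-adjusted copies per mL side by side, so any reporting
    convention can be compared.
    """
    rows = []
    for ch, k in positive_counts.items():
        lam, corrected = poisson_correct(k, n_wells)
        rows.append(
            QuantResult(
                channel=ch,
                positive_count=int(k),
                lambda_hat=lam,
                corrected_copies=corrected,
                copies_per_ml=copies_per_ml(
                    corrected, plasma_equiv_volume_ml, retention_fraction
                ),
                plasma_equiv_volume_ml=plasma_equiv_volume_ml,
                retention_fraction_used=retention_fraction,
            ).__dict__
        )
    return pd.DataFrame(rows)


@dataclass
class CurveMetrics:
    """Dilution-series performance of one channel."""

    slope: float
    intercept: float
    r_squared: float
    lod: float  # copies; NaN when nothing detected
    loq: float  # copies; NaN when no point detected in all replicates
    analytical_specificity_percent: float  # LOQ / background x 100


def standard_curve_metrics(
    nominal_copies,
    detected,
    background_copies: int,
) -> CurveMetrics:
    """Fit and characterize a detected-vs-expected dilution series.

    Parameters
    ----------
    nominal_copies, detected
        Parallel arrays over every (ladder point, replicate) observation.
        The 0-copy point is a negative control: excluded from the regression
        and from the LOD/LOQ search.
    background_copies
        Unmethylated background copies co-spiked into every reaction;
        denominator of the analytical specificity.
    """
    nominal = np.asarray(nominal_copies, dtype=float)
    det = np.asarray(detected, dtype=float)
    if nominal.shape != det.shape:
        raise DomainError("nominal_copies and detected must align")
    if background_copies <= 0:
        raise DomainError("background_copies must be > 0")
    nz = nominal > 0
    if len(np.unique(nominal[nz])) < 3:
        raise DomainError("need >= 3 distinct nonzero ladder points")
    if not np.any(det[nz] > 0):
        raise UndefinedCurveError("no positive detection at any nonzero point")

    fit = stats.linregress(nominal[nz], det[nz])
    r_squared = float(fit.rvalue**2)

    lod = np.nan
    loq = np.nan
    for level in np.unique(nominal[nz]):
        d = det[nominal == level]
        if np.isnan(lod) and np.any(d > 0):
            lod = float(level)
        if np.isnan(loq) and np.all(d > 0):
            loq = float(level)
    spec = float(loq / background_copies * 100.0) if np.isfinite(loq) else np.nan
    return CurveMetrics(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        lod=lod,
        loq=loq,
        analytical_specificity_percent=spec,
    )
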