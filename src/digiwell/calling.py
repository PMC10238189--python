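"""Two-population mixture fitting and five-sigma positive-well calling.

Each fluorescence channel's per-well intensity histogram is modelled as a
two-component location-scale (Gaussian) mixture: a large negative population
(background wells) and a bright positive population (wells containing at
least one amplified template).  The positivity threshold is the negative
mean plus five negative standard deviations, which allows roughly one
false-positive observation per million nanowell measurements under a
Gaussian negative population (upper-tail mass at 5 sigma ~ 2.87e-7).

The positive-component weight can be reported on the Poisson loading scale
(``lambda = -ln(1 - weight)``), reflecting that the fraction of occupied
wells under Poisson loading is ``1 - exp(-lambda)``; the likelihood itself is
the plain two-component mixture, which is equally expressive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import (
    DegenerateDataError,
    DomainError,
    SampleSizeError,
    SchemaError,
)

__all__ = [
    "MixtureConfig",
    "MixtureFit",
    "CallResult",
    "fit_intensity_mixture",
    "five_sigma_threshold",
    "call_wells",
]

NON_CHANNEL_COLUMNS = frozenset(
    {"module", "well_index", "row", "col", "x_px", "y_px", "aperture_pixels"}
)


@dataclass(frozen=True)
class MixtureConfig:
    """Knobs of the EM fit; defaults are deterministic (no random restarts)."""

    max_iter: int = 500
    tol: float = 1e-8  # relative change of the log-likelihood
    sd_floor: float = 1e-6  # ADU; SDs are floored here
    min_values: int = 100
    init_positive_weight: float = 0.02
    poisson_tied: bool = False  # report weight as 1 - exp(-lambda)
    #: EM iterations run on a deterministic stride subsample this large;
    #: the final iterations always use the full data (keeps very large
    #: inputs, e.g. multi-module pools, tractable without changing results
    #: beyond sampling noise of ~0.2% on the component SDs).
    max_fit_values: int = 200_000
    full_data_refinement_iter: int = 3


@dataclass
class MixtureFit:
    """Fitted two-population intensity mixture for one channel."""

    negative_mean: float
    negative_sd: float
    positive_mean: float
    positive_sd: float
    positive_weight: float
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_values: int = 0
    warnings: tuple[str, ...] = ()

    @property
    def lambda_hat(self) -> float:
        """Poisson loading rate implied by the positive-well fraction."""
        w = min(max(self.positive_weight, 0.0), 1.0 - 1e-15)
        return -np.log1p(-w)

    def as_dict(self) -> dict:
        return {
            "negative_mean": self.negative_mean,
            "negative_sd": self.negative_sd,
            "positive_mean": self.positive_mean,
            "positive_sd": self.positive_sd,
            "positive_weight": self.positive_weight,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "log_likelihood": self.log_likelihood,
        }


def _norm_logpdf(x, mean, sd):
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def _em_loop(x, params, config, max_iter):
    """Run EM from ``params`` = (m_neg, s_neg, m_pos, s_pos, w_pos)."""
    m_neg, s_neg, m_pos, s_pos, w_pos = params
    ll = -np.inf
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_p = np.stack(
            [
                np.log1p(-w_pos) + _norm_logpdf(x, m_neg, s_neg),
                np.log(max(w_pos, 1e-300)) + _norm_logpdf(x, m_pos, s_pos),
            ]
        )
        log_tot = logsumexp(log_p, axis=0)
        ll = float(log_tot.sum())
        resp_pos = np.exp(log_p[1] - log_tot)
        w_sum = resp_pos.sum()
        w_pos = float(w_sum / x.size)
        if w_sum > 0:
            m_pos = float((resp_pos * x).sum() / w_sum)
            s_pos = float(
                np.sqrt(max((resp_pos * (x - m_pos) ** 2).sum() / w_sum,
                            config.sd_floor**2))
            )
        resp_neg = 1.0 - resp_pos
        n_sum = resp_neg.sum()
        if n_sum > 0:
            m_neg = float((resp_neg * x).sum() / n_sum)
            s_neg = float(
                np.sqrt(max((resp_neg * (x - m_neg) ** 2).sum() / n_sum,
                            config.sd_floor**2))
            )
        if abs(ll - ll_prev) <= config.tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll
    return (m_neg, s_neg, m_pos, s_pos, w_pos), ll, it, converged


def fit_intensity_mixture(
    intensities, config: MixtureConfig | None = None
) -> MixtureFit:
    """EM fit of the two-component intensity mixture for one channel.

    Initialization is deterministic from data quantiles: the negative
    component starts at the 10th percentile with the (scaled) median absolute
    deviation as its spread, the positive component at the 99.9th percentile.
    Components are returned sorted by mean.  Convergence is declared when the
    relative change of the log-likelihood drops below ``tol`` (or after
    ``max_iter`` iterations).

    A post-fit identifiability guard collapses the fit to a single population
    when the fitted "positive" mean lies below the negative five-sigma
    threshold: two components that close describe one population, and the
    negative statistics are then the plain sample mean and SD.
    """
    config = config or MixtureConfig()
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < config.min_values:
        raise SampleSizeError(
            f"need >= {config.min_values} intensity values, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("all intensity values identical")

    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    spread = max(mad, config.sd_floor, 1e-3 * np.ptp(x))
    m_neg = float(np.percentile(x, 10.0))
    m_pos = float(np.percentile(x, 99.9))
    if m_pos <= m_neg:
        m_pos = m_neg + spread
    params = (m_neg, spread, m_pos, spread, config.init_positive_weight)

    it = 0
    if x.size > config.max_fit_values:
        stride = int(np.ceil(x.size / config.max_fit_values))
        params, _, sub_it, _ = _em_loop(
            x[::stride], params, config, config.max_iter
        )
        it += sub_it
        refine_iter = config.full_data_refinement_iter
    else:
        refine_iter = config.max_iter
    params, ll, full_it, converged = _em_loop(x, params, config, refine_iter)
    it += full_it
    m_neg, s_neg, m_pos, s_pos, w_pos = params

    if m_pos < m_neg:  # order components by mean
        m_neg, m_pos = m_pos, m_neg
        s_neg, s_pos = s_pos, s_neg
        w_pos = 1.0 - w_pos

    notes: list[str] = []
    if m_pos <= m_neg + 5.0 * s_neg or w_pos < 1.0 / x.size**2:
        # Not identifiable as two populations: a "positive" component below
        # the five-sigma threshold is indistinguishable from background.
        m_neg = float(x.mean())
        s_neg = float(max(x.std(), config.sd_floor))
        m_pos, s_pos, w_pos = m_neg, s_neg, 0.0
        notes.append("single-population fallback: components not separable")

    return MixtureFit(
        negative_mean=m_neg,
        negative_sd=max(s_neg, config.sd_floor),
        positive_mean=m_pos,
        positive_sd=max(s_pos, config.sd_floor),
        positive_weight=w_pos,
        converged=converged,
        n_iterations=it,
        log_likelihood=ll,
        n_values=int(x.size),
        warnings=tuple(notes),
    )


def five_sigma_threshold(fit: MixtureFit, sd_floor: float = 1e-6) -> float:
    """Positivity cutoff: negative mean + 5 x negative SD.

    Warns when the negative SD sits at the numerical floor (degenerate fit).
    """
    if fit.negative_sd <= sd_floor:
        warnings.warn(
            "negative SD at the epsilon floor; five-sigma threshold is degenerate"
        )
    return fit.negative_mean + 5.0 * fit.negative_sd


@dataclass
class CallResult:
    """Per-channel mixture fits, thresholds, well calls and positive counts."""

    fits: dict[str, MixtureFit]
    thresholds: dict[str, float]
    calls: pd.DataFrame  # module, well_index + one boolean column per channel
    positive_counts: dict[str, int]
    positive_counts_by_module: pd.DataFrame = field(default=None, repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            ch: {
                **self.fits[ch].as_dict(),
                "threshold": self.thresholds[ch],
                "positive_count": self.positive_counts[ch],
            }
            for ch in self.fits
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def call_wells(
    table: pd.DataFrame,
    fits: dict[str, MixtureFit],
    thresholds: dict[str, float] | None = None,
) -> CallResult:
    """Call positive wells per channel with the five-sigma thresholds.

    A well is positive when its mean intensity is strictly greater than the
    channel threshold (ties at the threshold stay negative — conservative
    false-positive control).
    """
    channel_cols = [c for c in table.columns if c not in NON_CHANNEL_COLUMNS]
    if set(fits) != set(channel_cols):
        raise SchemaError(
            f"channels in table {sorted(channel_cols)} do not match "
            f"fits {sorted(fits)}"
        )
    if thresholds is None:
        thresholds = {ch: five_sigma_threshold(fit) for ch, fit in fits.items()}
    base_cols = [c for c in ("module", "well_index") if c in table.columns]
    calls = table[base_cols].copy()
    counts: dict[str, int] = {}
    for ch in channel_cols:
        positive = table[ch].to_numpy() > thresholds[ch]
        calls[ch] = positive
        counts[ch] = int(positive.sum())
    by_module = None
    if "module" in calls.columns:
        by_module = calls.groupby("module")[channel_cols].sum().reset_index()
    return CallResult(
        fits=dict(fits),
        thresholds=dict(thresholds),
        calls=calls,
        positive_counts=counts,
        positive_counts_by_module=by_module,
    )
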