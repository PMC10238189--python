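"""Clinical evaluation of single markers and marker panels.

Single markers are thresholded on copies-per-mL by maximizing Youden's J
(TPR - FPR) over the midpoints between adjacent observed values.  Panels are
evaluated with leave-one-out cross-validated logistic regression: each
sample's case probability is predicted by a model trained on all other
samples, the held-out probabilities are swept as classification thresholds
to trace the ROC curve, and the AUC is reported with stratified bootstrap
percentile confidence intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, UndefinedMetricError

__all__ = [
    "DEFAULT_MARKERS",
    "SensSpec",
    "PanelEvaluation",
    "univariate_threshold",
    "sensitivity_specificity",
    "loocv_logistic",
    "roc_auc",
    "bootstrap_auc_ci",
    "panel_search",
    "evaluate_panel",
]

DEFAULT_MARKERS = ("SOX17", "CDO1", "TAC1", "HOXA7")


def _as_binary_labels(labels) -> np.ndarray:
    """Map labels to 1 = case, 0 = control."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu" and set(np.unique(arr)) <= {0, 1}:
        return arr.astype(int)
    if arr.dtype.kind in "US" or arr.dtype == object:
        allowed = {"case", "control"}
        values = {str(v) for v in np.unique(arr)}
        if not values <= allowed:
            raise SchemaError(f"labels must be case/control or 0/1, got {values}")
        return (arr == "case").astype(int)
    raise SchemaError("labels must be case/control strings or 0/1 integers")


def univariate_threshold(case_values, control_values) -> float:
    """Threshold maximizing Youden's J = TPR - FPR for calls value > t.

    Candidates are the midpoints between adjacent distinct observed values
    plus -inf and +inf; ties in J are broken toward the higher threshold
    (higher specificity).  With identical distributions the +inf threshold
    (call nothing positive, J = 0) is returned.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise DomainError("both groups must be non-empty")
    distinct = np.unique(np.concatenate([cases, controls]))
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    tpr = (cases[:, None] > candidates[None, :]).mean(axis=0)
    fpr = (controls[:, None] > candidates[None, :]).mean(axis=0)
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]  # ties -> higher threshold
    return float(candidates[best])


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SensSpec:
    """Clinical sensitivity/specificity, exact and integer-rounded percent."""

    sensitivity: float
    specificity: float
    sensitivity_rounded: int
    specificity_rounded: int
    n_cases: int
    n_controls: int


def sensitivity_specificity(calls, labels) -> SensSpec:
    """Sensitivity/specificity (%) of boolean calls against case/control labels.

    Rounded values use round-half-away-from-zero, the convention of printed
    clinical tables.
    """
    calls = np.asarray(calls, dtype=bool)
    y = _as_binary_labels(labels)
    if calls.shape != y.shape:
        raise SchemaError("calls and labels must align")
    n_cases = int(y.sum())
    n_controls = int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise UndefinedMetricError("need at least one case and one control")
    sens = 100.0 * calls[y == 1].sum() / n_cases
    spec = 100.0 * (~calls[y == 0]).sum() / n_controls
    return SensSpec(
        float(sens), float(spec),
        _round_half_away(sens), _round_half_away(spec),
        n_cases, n_controls,
    )


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` includes the intercept column.  A ridge jitter on the Hessian keeps
    the Newton step defined on separable folds (where the unpenalized MLE
    diverges); in that case the coefficients walk toward the separating
    direction until the step stalls and the last iterate is returned.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        mu = _sigmoid(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol * (1.0 + np.abs(beta).max()):
            converged = True
            break
    return beta, converged


def _design_matrix(df: pd.DataFrame, features) -> np.ndarray:
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise SchemaError(f"features not in cohort table: {missing}")
    cols = []
    for f in features:
        col = df[f].to_numpy(dtype=float)
        if np.ptp(col) == 0.0:
            warnings.warn(f"feature {f!r} is constant; dropped from the model")
            continue
        cols.append(col)
    if not cols:
        raise DomainError("no non-constant features left")
    return np.column_stack([np.ones(len(df))] + cols)


def loocv_logistic(cohort: pd.DataFrame, features, label_col: str = "label"):
    """Held-out case probability for each sample via leave-one-out CV.

    For each sample the logistic model is refit on all other samples and the
    left-out sample's predicted probability of being a case is recorded.
    Non-convergent folds warn and use the last IRLS iterate.
    """
    if len(cohort) < 10:
        raise DomainError("LOOCV needs at least 10 samples")
    X = _design_matrix(cohort, features)
    y = _as_binary_labels(cohort[label_col].to_numpy())
    n = len(cohort)
    probs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        beta, converged = _fit_logistic_irls(X[keep], y[keep])
        if not converged:
            warnings.warn(f"IRLS did not converge for held-out sample {i}")
        probs[i] = np.clip(_sigmoid(X[i] @ beta), 1e-12, 1.0 - 1e-12)
    return probs


def roc_auc(probabilities, labels) -> tuple[np.ndarray, float]:
    """ROC polyline and trapezoidal AUC from predicted probabilities.

    Thresholds sweep the distinct predicted values; tied predictions are
    grouped into a single ROC vertex, so the trapezoid rule counts ties as
    one half (the Mann-Whitney convention).  Returns (``roc_points`` as an
    (m, 2) array of (FPR, TPR) from (0,0) to (1,1), ``auc``).
    """
    scores = np.asarray(probabilities, dtype=float)
    y = _as_binary_labels(labels)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("ROC undefined with a single class")
    order = np.argsort(-scores, kind="mergesort")
    s, yy = scores[order], y[order]
    boundaries = np.flatnonzero(np.diff(s)) + 1  # group tied scores
    tp = np.concatenate([[0], np.cumsum(yy)[np.append(boundaries - 1, len(s) - 1)]])
    fp = np.concatenate([[0], np.cumsum(1 - yy)[np.append(boundaries - 1, len(s) - 1)]])
    fpr = fp / n0
    tpr = tp / n1
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def bootstrap_auc_ci(
    probabilities,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC.

    Cases and controls are resampled within class, so both classes are
    present in every resample.
    """
    if n_boot < 100:
        raise DomainError("n_boot must be >= 100")
    if not (0.0 < level < 1.0):
        raise DomainError("level must be in (0, 1)")
    scores = np.asarray(probabilities, dtype=float)
    y = _as_binary_labels(labels)
    case_scores = scores[y == 1]
    control_scores = scores[y == 0]
    if case_scores.size == 0 or control_scores.size == 0:
        raise UndefinedMetricError("need both classes for a bootstrap CI")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    boot_labels = np.concatenate(
        [np.ones(case_scores.size, int), np.zeros(control_scores.size, int)]
    )
    for b in range(n_boot):
        cs = case_scores[rng.integers(0, case_scores.size, case_scores.size)]
        ks = control_scores[rng.integers(0, control_scores.size, control_scores.size)]
        _, aucs[b] = roc_auc(np.concatenate([cs, ks]), boot_labels)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class PanelEvaluation:
    """Full evaluation of one marker panel on one cohort."""

    features: tuple[str, ...]
    probabilities: np.ndarray
    roc_points: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    operating_threshold: float
    sensitivity: float
    specificity: float
    n_boot: int
    seed: int
    per_marker: pd.DataFrame | None = field(default=None, repr=False)


def evaluate_panel(
    cohort: pd.DataFrame,
    markers=DEFAULT_MARKERS,
    covariates=(),
    label_col: str = "label",
    n_boot: int = 2000,
    seed: int = 0,
) -> PanelEvaluation:
    """LOOCV panel evaluation plus per-marker univariate metrics.

    The panel's reported sensitivity/specificity use the Youden-optimal
    threshold on the held-out probabilities.
    """
    features = tuple(markers) + tuple(covariates)
    y = _as_binary_labels(cohort[label_col].to_numpy())
    probs = loocv_logistic(cohort, features, label_col)
    points, auc = roc_auc(probs, y)
    lo, hi = bootstrap_auc_ci(probs, y, n_boot=n_boot, seed=seed)
    thr = univariate_threshold(probs[y == 1], probs[y == 0])
    ss = sensitivity_specificity(probs > thr, y)

    rows = []
    for m in markers:
        vals = cohort[m].to_numpy(dtype=float)
        t = univariate_threshold(vals[y == 1], vals[y == 0])
        m_ss = sensitivity_specificity(vals > t, y)
        rows.append(
            {
                "marker": m,
                "threshold": t,
                "sensitivity": m_ss.sensitivity,
                "specificity": m_ss.specificity,
                "sensitivity_rounded": m_ss.sensitivity_rounded,
                "specificity_rounded": m_ss.specificity_rounded,
            }
        )
    return PanelEvaluation(
        features=features,
        probabilities=probs,
        roc_points=points,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        operating_threshold=thr,
        sensitivity=ss.sensitivity,
        specificity=ss.specificity,
        n_boot=n_boot,
        seed=seed,
        per_marker=pd.DataFrame(rows),
    )


def panel_search(
    cohort: pd.DataFrame,
    candidate_markers=DEFAULT_MARKERS,
    label_col: str = "label",
    max_markers: int = 8,
) -> pd.DataFrame:
    """Rank every nonempty marker subset by LOOCV AUC.

    Ties are broken toward smaller subsets.  Exhaustive, so the candidate
    list is capped at ``max_markers``.
    """
    markers = list(candidate_markers)
    if len(markers) > max_markers:
        raise DomainError(
            f"{len(markers)} candidate markers exceed the exhaustive-search "
            f"limit of {max_markers}"
        )
    y = _as_binary_labels(cohort[label_col].to_numpy())
    rows = []
    for k in range(1, len(markers) + 1):
        for subset in itertools.combinations(markers, k):
            probs = loocv_logistic(cohort, subset, label_col)
            _, auc = roc_auc(probs, y)
            rows.append({"markers": subset, "n_markers": k, "loocv_auc": auc})
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["loocv_auc", "n_markers"], ascending=[False, True])
        .reset_index(drop=True)
    )
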