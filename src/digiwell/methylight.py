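"""Bulk MethyLight comparator: mean relative methylation from qPCR triplicates.

Each marker is assayed in triplicate against a reference-gene mean Ct.  The
per-replicate relative methylation is ``2**-(Ct_i - Ct_ref)`` and the summary
is the arithmetic mean over the three replicates.  A replicate with no
detected methylation is assigned Ct = 100, making its contribution
effectively (but not exactly) zero — the convention reduces bias relative to
dropping undetected replicates.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

__all__ = ["UNDETECTED_CT", "mean_relative_methylation", "process_ct_table"]

UNDETECTED_CT = 100.0

_UNDETECTED_TOKENS = {"", "nd", "na", "n/a", "undetected", "none"}


def _parse_ct(value) -> float:
    """A Ct value, or the Ct=100 convention for undetected replicates."""
    if value is None:
        return UNDETECTED_CT
    if isinstance(value, str):
        if value.strip().lower() in _UNDETECTED_TOKENS:
            return UNDETECTED_CT
        value = float(value)
    value = float(value)
    if math.isnan(value):
        return UNDETECTED_CT
    if not (0.0 < value <= UNDETECTED_CT):
        raise DomainError(f"detected Ct must lie in (0, {UNDETECTED_CT}], got {value}")
    return value


def mean_relative_methylation(target_cts, reference_mean_ct) -> float:
    """Mean 2^-dCt over exactly three target replicates.

    ``dCt_i = Ct_i - reference_mean_ct``; undetected replicates (None, NaN,
    "ND", empty) enter with Ct = 100.
    """
    if reference_mean_ct is None or (
        isinstance(reference_mean_ct, float) and math.isnan(reference_mean_ct)
    ):
        raise DomainError("reference_mean_ct is missing")
    ref = float(reference_mean_ct)
    if not math.isfinite(ref):
        raise DomainError("reference_mean_ct must be finite")
    cts = list(target_cts)
    if len(cts) != 3:
        raise SchemaError(f"exactly 3 target replicates required, got {len(cts)}")
    vals = [2.0 ** -(_parse_ct(ct) - ref) for ct in cts]
    return sum(vals) / 3.0


def process_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``mean_2dct`` column to a replicate table.

    Expects columns ``ct1, ct2, ct3, ref_mean_ct`` (plus any identifiers,
    e.g. sample_id and marker, which are passed through).
    """
    required = {"ct1", "ct2", "ct3", "ref_mean_ct"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    out["mean_2dct"] = [
        mean_relative_methylation((r.ct1, r.ct2, r.ct3), r.ref_mean_ct)
        for r in df.itertuples()
    ]
    return out
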