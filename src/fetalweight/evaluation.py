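"""Percentage-error evaluation of weight estimates.

A birth-weight estimate is conventionally "accepted" when it falls within
10% of the actual weight.  The evaluation report therefore buckets signed
percentage errors PE = 100*(estimated - actual)/actual into five bands —
over-estimation by 10–15% or >15%, accepted (|PE| < 10%), under-estimation
by 10–15% or >15% — and summarises accuracy as the mean absolute
percentage error (MPE).  Boundary convention: |PE| of exactly 10 or 15
falls in the 10–15% band (the accepted band is strictly < 10%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorReport",
    "BUCKET_ORDER",
    "percentage_error",
    "bucket_errors",
    "mpe_report",
]

BUCKET_ORDER = (
    "over_gt15",
    "over_10_15",
    "accepted_lt10",
    "under_10_15",
    "under_gt15",
)


@dataclass(frozen=True)
class ErrorReport:
    """Per-case signed percentage errors plus bucket and MPE summaries.

    ``buckets`` maps each band name to ``(count, percent)``; counts are
    exact, percents are 100*count/n rounded to 2 dp.  ``mpe_abs`` is the
    mean of |PE| (the headline accuracy figure); ``mpe_signed`` the mean of
    the signed PEs (bias).
    """

    per_case: np.ndarray
    mpe_abs: float
    mpe_signed: float
    buckets: dict
    n_total: int

    @property
    def accepted_percent(self) -> float:
        return self.buckets["accepted_lt10"][1]


def percentage_error(estimated_g: float, actual_g: float) -> float:
    """Signed percentage error; positive means overestimation."""
    if not actual_g > 0:
        raise ValueError("actual weight must be positive")
    return 100.0 * (estimated_g - actual_g) / actual_g


def _bucket_of(pe: float) -> str:
    mag = abs(pe)
    if mag < 10.0:
        return "accepted_lt10"
    side = "over" if pe > 0 else "under"
    return f"{side}_10_15" if mag <= 15.0 else f"{side}_gt15"


def bucket_errors(signed_percents) -> dict:
    """Count the five bands over a list of signed percentage errors.

    Returns ``{band: (count, percent)}`` with percents to 2 dp.
    """
    pes = np.asarray(list(signed_percents), dtype=float)
    if pes.size == 0:
        raise ValueError("empty error list")
    counts = {name: 0 for name in BUCKET_ORDER}
    for pe in pes:
        counts[_bucket_of(float(pe))] += 1
    n = pes.size
    return {name: (c, round(100.0 * c / n, 2)) for name, c in counts.items()}


def mpe_report(estimates, actuals) -> ErrorReport:
    """Full percentage-error report for paired estimate/actual weights."""
    est = np.asarray(list(estimates), dtype=float)
    act = np.asarray(list(actuals), dtype=float)
    if est.shape != act.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {act.shape}")
    if est.size == 0:
        raise ValueError("empty input")
    if np.any(act <= 0):
        raise ValueError("actual weights must be positive")
    pes = 100.0 * (est - act) / act
    return ErrorReport(
        per_case=pes,
        mpe_abs=float(np.mean(np.abs(pes))),
        mpe_signed=float(np.mean(pes)),
        buckets=bucket_errors(pes),
        n_total=int(pes.size),
    )
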