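"""External-validation statistics and Fisher comparison of prediction errors.

SEP is the bias-corrected standard error of prediction (m - 1 denominator,
the NIRS convention); the plain root-mean-square error of prediction is also
reported.  SEP can be expressed as a percentage of a model's applicability
range (its Min-Max estimate span) so errors of parameters on different
scales are comparable.  Two models validated on the same external set are
compared with a two-sided variance-ratio (Fisher) test on their SEPs with
(m - 1, m - 1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ValidationStats:
    m: int
    bias: float
    sep: float
    rmsep: float
    sep_percent: float
    rsq_val: float

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 validation samples")
        if self.sep < 0:
            raise ValueError("SEP must be non-negative")


@dataclass
class FisherComparison:
    f: float
    df: tuple
    alpha: float
    significant: bool
    p_value: float


def validation_stats(
    y_true,
    y_pred,
    applicability_range: tuple[float, float],
    range_normalization: str = "span",
) -> ValidationStats:
    """Bias, SEP, RMSEP, SEP% and validation R^2 for one external set.

    ``range_normalization`` chooses the SEP% denominator: ``"span"`` uses
    max - min of the applicability range, ``"mean"`` uses the range midpoint.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/reference length mismatch")
    m = len(y_true)
    if m < 2:
        raise ValueError("need at least 2 validation samples")
    lo, hi = applicability_range
    if range_normalization == "span":
        denom = hi - lo
    elif range_normalization == "mean":
        denom = (hi + lo) / 2.0
    else:
        raise ValueError("range_normalization must be 'span' or 'mean'")
    if denom <= 0:
        raise ValueError("degenerate applicability range")

    err = y_pred - y_true
    bias = float(err.mean())
    sep = float(np.sqrt(((err - bias) ** 2).sum() / (m - 1)))
    rmsep = float(np.sqrt((err**2).mean()))
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    rsq = 1.0 - float((err**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return ValidationStats(
        m=m,
        bias=bias,
        sep=sep,
        rmsep=rmsep,
        sep_percent=100.0 * sep / denom,
        rsq_val=rsq,
    )


def fisher_compare(
    stats_a: ValidationStats, stats_b: ValidationStats, alpha: float = 0.05
) -> FisherComparison:
    """Two-sided F test on two SEPs measured on same-sized validation sets.

    F places the larger SEP squared in the numerator; significance is tested
    against the F distribution with (m - 1, m - 1) degrees of freedom at
    level ``alpha`` (two-sided, so the upper critical point is at
    1 - alpha/2).
    """
    if stats_a.m != stats_b.m:
        raise ValueError("Fisher comparison needs equal validation sizes")
    lo, hi = sorted((stats_a.sep, stats_b.sep))
    if lo <= 0:
        raise ValueError("zero SEP in the Fisher ratio denominator")
    f = (hi / lo) ** 2
    df = (stats_a.m - 1, stats_b.m - 1)
    crit = sps.f.ppf(1.0 - alpha / 2.0, *df)
    p = 2.0 * sps.f.sf(f, *df)
    return FisherComparison(
        f=float(f), df=df, alpha=alpha, significant=bool(f > crit), p_value=float(min(1.0, p))
    )


def build_report(runs: list[dict]) -> pd.DataFrame:
    """Assemble the study table: one row per (set, parameter).

    Each run dict carries set/parameter labels, the pretreatment string, the
    calibration stats, the validation stats and (for reduced sets) the
    Fisher comparison against the full-calibration model.  SEP carries an
    asterisk in the rendered column iff the comparison is significant.
    """
    if not runs:
        raise ValueError("no completed runs to report")
    rows = []
    for r in runs:
        cal = r["calibration_stats"]
        val = r["validation_stats"]
        fisher = r.get("fisher")
        sig = bool(fisher.significant) if fisher is not None else False
        rows.append(
            {
                "set": r["set"],
                "parameter": r["parameter"],
                "pretreatment": r["pretreatment"],
                "N": cal.n,
                "T_outliers": cal.n_t_outliers,
                "Min": round(cal.min_estimate, 2),
                "Max": round(cal.max_estimate, 2),
                "RSQ": round(cal.rsq, 2),
                "SECV": round(cal.secv, 3),
                "SEP": round(val.sep, 3),
                "SEP_percent": round(val.sep_percent, 1),
                "bias": round(val.bias, 3),
                "significant_vs_FC": sig,
                "SEP_label": f"{val.sep:.2f}*" if sig else f"{val.sep:.2f}",
            }
        )
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of the study table."""
    cols = [
        "set",
        "parameter",
        "pretreatment",
        "N",
        "T_outliers",
        "Min",
        "Max",
        "RSQ",
        "SECV",
        "SEP_label",
    ]
    return report[cols].rename(columns={"SEP_label": "SEP"}).to_string(index=False)


__all__ = [
    "ValidationStats",
    "FisherComparison",
    "validation_stats",
    "fisher_compare",
    "build_report",
    "render_report",
]
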