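"""Paired-condition hypothesis testing with a normality gate.

The decision procedure for each feature is: compute within-subject
differences (condition1 - condition2); if the differences contain an
outlier (beyond 1.5*IQR) or fail the Shapiro-Wilk normality test at the
chosen alpha, fall back to the Wilcoxon signed-rank test, otherwise use the
paired t-test. Descriptives mirror the branch: mean +/- SD for the t branch,
median (P25, P75) for the Wilcoxon branch.

The Wilcoxon p-value is exact (distribution of the positive-rank sum
enumerated by dynamic programming, valid under average-rank ties) for up to
25 non-zero differences, and a normal approximation with continuity
correction above that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateInputError, InsufficientDataError, InvalidArgumentError

__all__ = [
    "PairedSample",
    "PairedTestResult",
    "shapiro_wilk",
    "paired_t",
    "wilcoxon_signed_rank",
    "compare_conditions",
    "summarize_features",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedSample:
    ids: np.ndarray
    x: np.ndarray  # condition 1 (focused)
    y: np.ndarray  # condition 2 (distracted)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise InvalidArgumentError("ids, x, y must have equal lengths")
        if len(np.unique(self.ids)) != len(self.ids):
            raise InvalidArgumentError("subject ids must be unique")

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class PairedTestResult:
    test_name: str  # "paired_t" | "wilcoxon"
    statistic: float  # t or z
    p: float
    sw_p: float | None
    descriptive_1: dict
    descriptive_2: dict
    n: int


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation, via scipy)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise InsufficientDataError("Shapiro-Wilk needs n >= 3")
    if n > 50:
        raise InvalidArgumentError("Shapiro-Wilk gate intended for n <= 50")
    if np.ptp(values) == 0:
        raise DegenerateInputError("all values identical; normality test undefined")
    res = sstats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def _mean_sd(values: np.ndarray) -> dict:
    return {"mean": float(np.mean(values)), "sd": float(np.std(values, ddof=1))}


def _median_iqr(values: np.ndarray) -> dict:
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])  # type-7 linear
    return {"median": float(q50), "p25": float(q25), "p75": float(q75)}


def paired_t(sample: PairedSample) -> PairedTestResult:
    """Classic paired t-test on the differences, two-sided."""
    d = sample.differences
    if d.size < 2:
        raise InsufficientDataError("paired t-test needs n >= 2")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateInputError("differences have zero variance")
    n = d.size
    t = float(np.mean(d)) / (sd / np.sqrt(n))
    p = 2.0 * float(sstats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(
        test_name="paired_t", statistic=t, p=p, sw_p=None,
        descriptive_1=_mean_sd(sample.x), descriptive_2=_mean_sd(sample.y), n=n,
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the positive-rank sum, given the realized ranks.

    Ranks may be half-integers (average-rank ties); they are doubled to
    integers and the distribution of the doubled rank sum over all 2^n sign
    assignments is built by polynomial multiplication.
    """
    ranks2 = np.round(ranks * 2).astype(int)
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    p_le = float(counts[: w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(sample: PairedSample) -> PairedTestResult:
    """Wilcoxon signed-rank test on the paired differences, two-sided.

    Zero differences are dropped; ties get average ranks. The z statistic
    (normal approximation with continuity correction and tie correction) is
    always reported; the p-value is exact for <= 25 non-zero differences.
    """
    d = sample.differences
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise (
            DegenerateInputError("all differences are zero")
            if d.size == 0
            else InsufficientDataError("Wilcoxon needs >= 5 non-zero differences")
        )
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_sizes**3 - tie_sizes) / 48.0
    if var_w <= 0:
        raise DegenerateInputError("degenerate rank distribution")
    cc = 0.5 * np.sign(w_plus - mean_w)
    z = (w_plus - mean_w - cc) / np.sqrt(var_w) if w_plus != mean_w else 0.0
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = 2.0 * float(sstats.norm.sf(abs(z)))
    return PairedTestResult(
        test_name="wilcoxon", statistic=float(z), p=p, sw_p=None,
        descriptive_1=_median_iqr(sample.x), descriptive_2=_median_iqr(sample.y), n=len(sample),
    )


def _has_outlier(d: np.ndarray) -> bool:
    q1, q3 = np.quantile(d, [0.25, 0.75])
    iqr = q3 - q1
    return bool(np.any((d < q1 - 1.5 * iqr) | (d > q3 + 1.5 * iqr)))


def compare_conditions(sample: PairedSample, alpha: float = 0.05) -> PairedTestResult:
    """Shapiro-Wilk-gated paired comparison (see module docstring)."""
    if not (0 < alpha < 1):
        raise InvalidArgumentError("alpha must be in (0, 1)")
    d = sample.differences
    if np.ptp(d) == 0:
        raise DegenerateInputError("differences have zero variance")
    _, sw_p = shapiro_wilk(d)
    use_t = (sw_p >= alpha) and not _has_outlier(d)
    result = paired_t(sample) if use_t else wilcoxon_signed_rank(sample)
    result.sw_p = sw_p
    return result


def summarize_features(
    features: pd.DataFrame,
    alpha: float = 0.05,
    subject_col: str = "subject_id",
    condition_col: str = "condition",
    focused_label: str = "focused",
    distracted_label: str = "distracted",
) -> pd.DataFrame:
    """Per-feature paired comparison table (one row per feature column).

    ``features`` holds one row per (subject, condition); every other numeric
    column is tested. Degenerate features yield NaN statistics.
    """
    wide = features.pivot(index=subject_col, columns=condition_col)
    rows = []
    value_cols = [
        c for c in features.columns
        if c not in (subject_col, condition_col)
        and pd.api.types.is_numeric_dtype(features[c])
    ]
    for col in value_cols:
        x = wide[(col, focused_label)].to_numpy(dtype=float)
        y = wide[(col, distracted_label)].to_numpy(dtype=float)
        ids = wide.index.to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        sample = PairedSample(ids[ok], x[ok], y[ok])
        try:
            res = compare_conditions(sample, alpha=alpha)
            rows.append({
                "feature": col, "test_name": res.test_name,
                "statistic": res.statistic, "p": res.p, "sw_p": res.sw_p,
                "n": res.n,
                "descriptive_1": _format_descr(res.descriptive_1),
                "descriptive_2": _format_descr(res.descriptive_2),
                "significant": res.p < alpha,
            })
        except (DegenerateInputError, InsufficientDataError):
            rows.append({
                "feature": col, "test_name": "none",
                "statistic": float("nan"), "p": float("nan"), "sw_p": float("nan"),
                "n": int(ok.sum()), "descriptive_1": "", "descriptive_2": "",
                "significant": False,
            })
    return pd.DataFrame(rows)


def _format_descr(d: dict) -> str:
    if "mean" in d:
        return f"{d['mean']:.2f} ± {d['sd']:.2f}"
    return f"{d['median']:.2f} ({d['p25']:.2f}, {d['p75']:.2f})"
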