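"""Fisher's-discriminant metric ranking, the Sickle Score gate, and the
percent-sickled endpoint.

The separation statistic between two samples of a metric is

    Fd = |mean_a - mean_b| / (sd_a + sd_b)

with sample standard deviations (n-1 denominator).  This matches the
"discriminant of means" convention of the imaging-cytometry software
family; a pooled-SD alternative is available via ``denominator``.

The sickle gate is calibrated on a non-sickling control population at a
target spillover (default 10%): the threshold is the (1 - spillover)
linear-interpolation quantile of the control scores, and an event
counts as sickled when its score is strictly above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FdRanking",
    "SickleGate",
    "GroupComparison",
    "fishers_discriminant",
    "rank_metrics",
    "sickle_score",
    "calibrate_sickle_gate",
    "percent_sickled",
    "compare_groups_t",
    "DEFAULT_METRICS",
]

DEFAULT_METRICS = [
    "area_um2",
    "length_um",
    "thickness_min_um",
    "thickness_max_um",
    "shape_ratio",
    "symmetry2",
    "aspect_ratio",
    "circularity",
    "h_contrast",
    "h_entropy",
    "focus_score",
    "mean_brightfield",
    "integrated_brightfield",
    "sickle_score",
]


def fishers_discriminant(
    values_a, values_b, denominator: str = "sum_sd"
) -> float:
    """Fisher's discriminant of means between two samples of one metric.

    ``denominator="sum_sd"`` (default): |mu_a - mu_b| / (sd_a + sd_b);
    ``"pooled"``: |mu_a - mu_b| / pooled SD.  Returns +inf when both
    samples are constant but differ, 0 when they are the same constant.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 finite values")
    num = abs(a.mean() - b.mean())
    if denominator == "sum_sd":
        den = a.std(ddof=1) + b.std(ddof=1)
    elif denominator == "pooled":
        den = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
    else:
        raise ValueError("denominator must be 'sum_sd' or 'pooled'")
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / den)


@dataclass
class FdRanking:
    """Metrics sorted by descending Fisher's discriminant."""

    ranking: list[tuple[str, float]]
    population_a: str = "a"
    population_b: str = "b"

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.ranking[:k]]

    def fd(self, metric: str) -> float:
        for name, value in self.ranking:
            if name == metric:
                return value
        raise KeyError(metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["metric", "fd"])


def rank_metrics(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metrics: list[str] | None = None,
    *,
    names: tuple[str, str] = ("a", "b"),
    denominator: str = "sum_sd",
) -> FdRanking:
    """Rank candidate metrics by their two-class Fisher's discriminant.

    Ties are broken alphabetically by metric name.
    """
    metrics = list(metrics) if metrics is not None else list(DEFAULT_METRICS)
    for m in metrics:
        if m not in table_a.columns or m not in table_b.columns:
            raise ValueError(f"metric {m!r} absent from one of the tables")
    pairs = [
        (m, fishers_discriminant(table_a[m], table_b[m], denominator=denominator))
        for m in metrics
    ]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return FdRanking(ranking=pairs, population_a=names[0], population_b=names[1])


def sickle_score(features) -> float | pd.Series:
    """Sickle Score = Symmetry 2 / Shape Ratio (from the brightfield mask).

    Accepts a single feature record (mapping) or a feature table.
    Degenerate events or non-positive shape ratios yield NaN (flagged
    absent), never a silent zero.
    """
    if isinstance(features, pd.DataFrame):
        sr = features["shape_ratio"]
        s2 = features["symmetry2"]
        out = s2 / sr.where(sr > 0)
        if "degenerate" in features.columns:
            out = out.where(~features["degenerate"].astype(bool))
        return out
    sr = features["shape_ratio"]
    s2 = features["symmetry2"]
    if features.get("degenerate", False) or not sr > 0:
        return float("nan")
    return float(s2 / sr)


@dataclass(frozen=True)
class SickleGate:
    """Threshold on the Sickle Score calibrated at a target spillover."""

    threshold: float
    spillover: float = 0.10
    calibration_population: str = ""
    n_calibration: int = 0
    degenerate: bool = False  # constant calibration scores

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "spillover": self.spillover,
            "calibration_population": self.calibration_population,
            "n_calibration": self.n_calibration,
            "degenerate": self.degenerate,
        }

    @staticmethod
    def from_dict(d: dict) -> "SickleGate":
        return SickleGate(
            threshold=d["threshold"],
            spillover=d.get("spillover", 0.10),
            calibration_population=d.get("calibration_population", ""),
            n_calibration=d.get("n_calibration", 0),
            degenerate=d.get("degenerate", False),
        )


def calibrate_sickle_gate(
    control_scores, spillover: float = 0.10, population: str = "control"
) -> SickleGate:
    """Set the sickle gate so ~``spillover`` of a non-sickling control
    population scores positive.

    The threshold is the (1 - spillover) linear-interpolation quantile
    of the finite control scores.
    """
    if not 0.0 < spillover < 0.5:
        raise ValueError("spillover must be in (0, 0.5)")
    s = np.asarray(control_scores, dtype=np.float64)
    s = s[np.isfinite(s)]
    if len(s) < 100:
        raise ValueError(f"need >= 100 finite control scores (got {len(s)})")
    thr = float(np.quantile(s, 1.0 - spillover))
    degenerate = bool(s.min() == s.max())
    return SickleGate(
        threshold=thr,
        spillover=spillover,
        calibration_population=population,
        n_calibration=int(len(s)),
        degenerate=degenerate,
    )


def percent_sickled(scores, gate: SickleGate) -> float:
    """Fraction of finite scores strictly above the gate threshold.

    Flagged (NaN) events are excluded from numerator and denominator.
    """
    s = np.asarray(scores, dtype=np.float64)
    s = s[np.isfinite(s)]
    if len(s) == 0:
        raise ValueError("no finite scores to gate")
    return float((s > gate.threshold).mean())


@dataclass
class GroupComparison:
    """Two-group test result with the summary statistics reported alongside."""

    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    mean_a: float | None = None
    mean_b: float | None = None
    sd_a: float | None = None
    sd_b: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def compare_groups_t(percents_a, percents_b, equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t test on per-trial endpoint values.

    Equal-variance (Student) form by default; Welch via
    ``equal_var=False``.
    """
    a = np.asarray(percents_a, dtype=np.float64)
    b = np.asarray(percents_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 trials per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="students_t" if equal_var else "welch_t",
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
    )
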