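"""Per-cell sickling-event detection in time-lapse data and the kinetic
endpoints: percent sickled, median time to sickling, delay time,
maximum sickling rate, with the survival-style group tests.

Frames are scored at a fixed interval (default every 256th frame; at
4 fps that is one comparison per 64 s).  A cell scores positive at the
first sampled frame where its mask has changed by more than
``change_threshold`` (1 - intersection/union against the previous
sampled frame) and the change persists at the next sampled frame; the
event time is the time of the detecting sampled frame, so every
detected time is a multiple of the sampling interval and never precedes
the true transition.  Cells without a qualifying change are
right-censored at the end of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .scoring import GroupComparison
from .simulate.video import VideoField

__all__ = [
    "KineticsSummary",
    "sample_frames",
    "detect_events",
    "cumulative_curve",
    "plot_cumulative_curves",
    "kinetics_summary",
    "gehan_breslow_wilcoxon",
    "wilcoxon_times",
]

#: brightfield threshold between interior (~0.65) and background (~0.8)
_MASK_LEVEL_OFFSET = 0.0775


def sample_frames(n_frames: int, interval_frames: int = 256) -> np.ndarray:
    """Sampled frame indices 0, interval, 2*interval, ...

    The last partial interval is dropped.
    """
    if interval_frames < 1:
        raise ValueError("interval_frames must be >= 1")
    if interval_frames >= n_frames:
        raise ValueError(
            f"interval_frames={interval_frames} must be < total frames {n_frames}"
        )
    return np.arange(0, n_frames, interval_frames)


def _window_mask(window: np.ndarray) -> np.ndarray:
    """Cheap object mask for a single-cell video window.

    Fixed threshold halfway between interior and background grey levels
    (the video renderer's levels are known), then hole filling so the
    dark rim and interior form one solid object.
    """
    level = float(np.median(window)) - _MASK_LEVEL_OFFSET
    return ndi.binary_fill_holes(window < level)


def _iou_change(m0: np.ndarray, m1: np.ndarray) -> float:
    union = np.logical_or(m0, m1).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(m0, m1).sum()
    return 1.0 - inter / union


def detect_events(
    video: VideoField,
    interval_frames: int = 256,
    change_threshold: float = 0.25,
    max_lost_fraction: float = 0.20,
) -> pd.DataFrame:
    """Detect per-cell sickling events on the sampled frame series.

    Returns a timelines table: ``cell_id``, ``time_min`` (NaN when
    censored), ``censored``, ``detect_frame``, ``flagged`` (segmentation
    lost in more than ``max_lost_fraction`` of the cell's frames; such
    cells are excluded from downstream summaries, not censored).
    """
    indices = sample_frames(video.n_frames, interval_frames)
    if len(indices) < 2:
        raise ValueError("need >= 2 sampled frames")
    n_cells = len(video.truth)
    T = video.config.duration_min

    masks_prev: list[np.ndarray | None] = [None] * n_cells
    ref_masks: list[np.ndarray | None] = [None] * n_cells  # pre-change reference
    pending: dict[int, tuple[int, float]] = {}  # cell -> (frame_idx, time)
    event_time = np.full(n_cells, np.nan)
    event_frame = np.full(n_cells, -1, dtype=int)
    lost_counts = np.zeros(n_cells, dtype=int)

    for j, idx in enumerate(indices):
        img = video.frame(int(idx))
        t = video.frame_time_min(int(idx))
        for k in range(n_cells):
            if event_frame[k] >= 0 and k not in pending:
                continue
            win = video.cell_window(img, k)
            m = _window_mask(win)
            if m.sum() < 16:
                lost_counts[k] += 1
                continue
            if k in pending:
                # persistence check against the pre-change reference mask
                fidx, ftime = pending.pop(k)
                if _iou_change(ref_masks[k], m) > change_threshold:
                    event_frame[k] = fidx
                    event_time[k] = ftime
                else:
                    masks_prev[k] = m
                continue
            if masks_prev[k] is not None and event_frame[k] < 0:
                if _iou_change(masks_prev[k], m) > change_threshold:
                    if j == len(indices) - 1:
                        event_frame[k] = int(idx)  # last interval: persistence exempt
                        event_time[k] = t
                    else:
                        ref_masks[k] = masks_prev[k]
                        pending[k] = (int(idx), t)
                        continue
            masks_prev[k] = m
    # pending cells whose confirmation frame never came (lost masks): no event
    flagged = lost_counts / len(indices) > max_lost_fraction

    out = pd.DataFrame(
        {
            "cell_id": video.truth["cell_id"].to_numpy(),
            "time_min": event_time,
            "censored": ~np.isfinite(event_time) | (event_time > T),
            "detect_frame": event_frame,
            "flagged": flagged,
        }
    )
    out.loc[out["censored"], "time_min"] = np.nan
    out.attrs["duration_min"] = T
    out.attrs["interval_s"] = interval_frames / video.config.fps
    return out


def cumulative_curve(timelines: pd.DataFrame, duration_min: float | None = None) -> pd.DataFrame:
    """Right-continuous step function of sickled fraction vs time.

    Starts at 0; its value at the recording end equals the percent
    sickled.  Flagged cells are excluded.
    """
    tl = _clean(timelines)
    if len(tl) == 0:
        raise ValueError("no timelines")
    T = duration_min if duration_min is not None else tl.attrs.get("duration_min", 30.0)
    events = np.sort(tl.loc[~tl["censored"], "time_min"].to_numpy())
    n = len(tl)
    times = [0.0]
    fracs = [0.0]
    for t, c in zip(*np.unique(events, return_counts=True)):
        times.append(float(t))
        fracs.append(fracs[-1] + c / n)
    if not times or times[-1] < T:
        times.append(float(T))
        fracs.append(fracs[-1])
    return pd.DataFrame({"time_min": times, "sickled_fraction": fracs})


@dataclass
class KineticsSummary:
    """Kinetic endpoints of one trial or pooled group."""

    pct_sickled: float
    median_time_min: float | None
    delay_min: float | None
    max_rate_per_sec: float
    n_cells: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _clean(timelines: pd.DataFrame) -> pd.DataFrame:
    tl = timelines
    if "flagged" in tl.columns:
        kept = tl[~tl["flagged"].astype(bool)].copy()
        kept.attrs.update(tl.attrs)
        return kept
    return tl


def _lower_median(x: np.ndarray) -> float:
    xs = np.sort(x)
    return float(xs[(len(xs) - 1) // 2])


def kinetics_summary(
    timelines: pd.DataFrame,
    duration_min: float | None = None,
    interval_s: float | None = None,
    smooth_intervals: int = 1,
) -> KineticsSummary:
    """Percent sickled, median time (lower median over event times only),
    delay (first event time) and maximum sickling rate.

    The maximum rate is the largest per-interval event fraction divided
    by the interval length in seconds (cells/total cells/sec), computed
    on raw sampled intervals; ``smooth_intervals > 1`` applies a moving
    average over that many intervals first.
    """
    tl = _clean(timelines)
    if len(tl) == 0:
        raise ValueError("no timelines")
    T = duration_min if duration_min is not None else tl.attrs.get("duration_min", 30.0)
    dt_s = interval_s if interval_s is not None else tl.attrs.get("interval_s", 64.0)
    n = len(tl)
    events = tl.loc[~tl["censored"], "time_min"].to_numpy(dtype=np.float64)
    pct = len(events) / n
    if len(events) == 0:
        return KineticsSummary(0.0, None, None, 0.0, n)
    median = _lower_median(events)
    delay = float(events.min())
    grid = np.arange(0.0, T * 60.0 + dt_s, dt_s)  # seconds
    counts, _ = np.histogram(events * 60.0, bins=grid)
    if smooth_intervals > 1 and len(counts) >= smooth_intervals:
        kernel = np.ones(smooth_intervals) / smooth_intervals
        counts = np.convolve(counts, kernel, mode="valid")
    max_rate = float(counts.max() / n / dt_s)
    return KineticsSummary(
        pct_sickled=float(pct),
        median_time_min=median,
        delay_min=delay,
        max_rate_per_sec=max_rate,
        n_cells=n,
    )


def plot_cumulative_curves(groups: dict[str, pd.DataFrame], ax=None, out_path=None):
    """Step plot of mean percent sickled vs time for one or more groups.

    ``groups`` maps a label to a timelines table.  Returns the axes;
    saves to ``out_path`` when given.
    """
    import matplotlib

    if out_path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, tl in groups.items():
        curve = cumulative_curve(tl)
        ax.step(
            curve["time_min"], 100 * curve["sickled_fraction"], where="post", label=label
        )
    ax.set_xlabel("time after induction (min)")
    ax.set_ylabel("percent sickled")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
    return ax


def _km_table(times_a, cens_a, times_b, cens_b):
    """At-risk / event counts per distinct event time for two groups."""
    ta = np.asarray(times_a, dtype=np.float64)
    tb = np.asarray(times_b, dtype=np.float64)
    ca = np.asarray(cens_a, dtype=bool)
    cb = np.asarray(cens_b, dtype=bool)
    event_times = np.unique(np.concatenate([ta[~ca], tb[~cb]]))
    rows = []
    for t in event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        d_a = int(((ta == t) & ~ca).sum())
        d_b = int(((tb == t) & ~cb).sum())
        rows.append((t, n_a, n_b, d_a, d_b))
    return rows


def gehan_breslow_wilcoxon(timelines_a: pd.DataFrame, timelines_b: pd.DataFrame) -> GroupComparison:
    """Gehan-Breslow-Wilcoxon test between two groups of cell timelines.

    A weighted log-rank statistic with weight equal to the total number
    at risk at each event time, so early events (the bulk of sickling)
    dominate; chi-square on 1 df, two-sided.  Censoring at the
    recording end is honoured.  With no events in either group the
    statistic is 0 and p = 1.
    """
    a, b = _clean(timelines_a), _clean(timelines_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 cells per group")
    Ta = a.attrs.get("duration_min", 30.0)
    ta = a["time_min"].fillna(Ta).to_numpy(dtype=np.float64)
    tb = b["time_min"].fillna(b.attrs.get("duration_min", Ta)).to_numpy(dtype=np.float64)
    ca = a["censored"].to_numpy(dtype=bool)
    cb = b["censored"].to_numpy(dtype=bool)

    U = 0.0
    V = 0.0
    for t, n_a, n_b, d_a, d_b in _km_table(ta, ca, tb, cb):
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        w = float(n)
        U += w * (d_a - d * n_a / n)
        V += w * w * d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if V <= 0:
        return GroupComparison(0.0, 1.0, "gehan_breslow_wilcoxon", len(a), len(b))
    chi2 = U * U / V
    p = float(stats.chi2.sf(chi2, df=1))
    return GroupComparison(float(chi2), p, "gehan_breslow_wilcoxon", len(a), len(b))


def wilcoxon_times(event_times_a, event_times_b) -> GroupComparison:
    """Two-sided rank-sum test on uncensored event times.

    Exact for small untied samples; for the heavily tied sampling grid,
    the normal approximation with mid-rank tie correction is used.
    """
    a = np.asarray(event_times_a, dtype=np.float64)
    b = np.asarray(event_times_b, dtype=np.float64)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("need >= 1 event per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="wilcoxon_rank_sum",
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.median(a)),
        mean_b=float(np.median(b)),
    )
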