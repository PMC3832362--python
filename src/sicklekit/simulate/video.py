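"""Sickling time-lapse simulation: per-cell event times and video rendering.

The kinetics model is delay + exponential hazard: after chemical
deoxygenation there is an absolute delay ``delay_min`` before any cell
can sickle (the polymerisation lag), then each *susceptible* cell
(probability ``susceptible_fraction``) sickles at

    t = delay_min + Exponential(rate ``hazard_per_min``).

Cells whose time exceeds the recording duration, and non-susceptible
cells, are right-censored at the end of the recording.  The expected
observed sickled fraction is the truncation law

    p_s * (1 - exp(-lambda * (T - t0))).

Rendering: cells sit at static positions on a grid (cells settle in the
dish; no motion model).  Each cell is drawn as a disc until its true
time, then morphs into a crescent over ``transition_sec`` seconds
("rapid, typically within a few seconds") and remains sickled.  Frame
``i`` is a pure function of (config, i): per-frame noise is seeded from
``SeedSequence(entropy=seed, spawn_key=(1, i))`` and per-cell geometry
from ``spawn_key=(0, k)``, so rendering any subset of frame indices is
pixel-identical to dense rendering at those indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shapes import _BG, _NOISE_SIGMA, ShapeParams, render_shape_mask
from scipy import ndimage as ndi

__all__ = [
    "KineticsConfig",
    "FieldLayout",
    "VideoField",
    "simulate_sickling_times",
    "render_video",
]


@dataclass(frozen=True)
class KineticsConfig:
    """Study conditions of one sickling video trial."""

    n_cells: int = 568
    susceptible_fraction: float = 0.54
    delay_min: float = 4.3
    hazard_per_min: float = 0.165
    duration_min: float = 30.0
    fps: float = 4.0
    transition_sec: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.susceptible_fraction <= 1.0:
            raise ValueError("susceptible_fraction must be in [0, 1]")
        if self.delay_min >= self.duration_min:
            raise ValueError("delay_min must be < duration_min")
        if self.hazard_per_min <= 0:
            raise ValueError("hazard_per_min must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min * 60.0 * self.fps))


@dataclass(frozen=True)
class FieldLayout:
    """Static grid layout of cells in the imaging field."""

    crop_px: int = 44
    pixel_size_um: float = 0.5
    field_px: int | None = None  # auto square grid when None


def simulate_sickling_times(config: KineticsConfig) -> pd.DataFrame:
    """Ground-truth sickling times for one trial.

    Returns one row per cell: ``susceptible``, ``true_time_min`` (inf
    for non-susceptible cells) and ``censored`` (no event within the
    recording window).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)))
    susceptible = rng.random(config.n_cells) < config.susceptible_fraction
    times = np.full(config.n_cells, np.inf)
    times[susceptible] = config.delay_min + rng.exponential(
        1.0 / config.hazard_per_min, int(susceptible.sum())
    )
    truth = pd.DataFrame(
        {
            "cell_id": [f"cell{k:04d}" for k in range(config.n_cells)],
            "susceptible": susceptible,
            "true_time_min": times,
            "censored": times > config.duration_min,
        }
    )
    truth.attrs["seed"] = config.seed
    return truth


class VideoField:
    """Lazy time-lapse renderer for one trial.

    Frames are rendered on demand; ``frame(i)`` is deterministic in
    (config, layout, i), so sampling every 256th frame gives exactly the
    pixels the dense video would have at those indices.
    """

    def __init__(self, truth: pd.DataFrame, config: KineticsConfig, layout: FieldLayout):
        self.truth = truth.reset_index(drop=True)
        self.config = config
        self.layout = layout
        n = len(self.truth)
        crop = layout.crop_px
        if layout.field_px is None:
            n_cols = int(np.ceil(np.sqrt(n)))
            field_px = n_cols * crop
        else:
            field_px = layout.field_px
            n_cols = field_px // crop
            if n_cols * (field_px // crop) < n:
                need = int(np.ceil(np.sqrt(n))) * crop
                raise ValueError(
                    f"cells would overlap at this density: field_px={field_px} fits "
                    f"{n_cols * (field_px // crop)} non-overlapping cells < {n}; "
                    f"use field_px >= {need}"
                )
        self.field_px = field_px
        self.n_cols = n_cols
        rows = np.arange(n) // n_cols
        cols = np.arange(n) % n_cols
        self.centers = pd.DataFrame(
            {
                "cell_id": self.truth["cell_id"],
                "row": rows * crop + crop // 2,
                "col": cols * crop + crop // 2,
            }
        )
        # per-cell geometry: a disc that will morph into a crescent
        self._params = []
        for k in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(0, k))
            )
            self._params.append(
                ShapeParams(
                    "crescent",
                    size_um=float(np.clip(rng.normal(8.0, 0.3), 7.0, 9.0)),
                    elongation=float(np.clip(rng.normal(2.8, 0.15), 2.2, 3.4)),
                    curvature=float(np.clip(rng.normal(0.7, 0.05), 0.5, 0.9)),
                    orientation_rad=rng.uniform(0, np.pi),
                )
            )
        self._crop_cache: dict[tuple[int, float], np.ndarray] = {}

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def frame_time_min(self, index: int) -> float:
        return index / self.config.fps / 60.0

    def _morph_at(self, k: int, t_min: float) -> float:
        t_true = self.truth["true_time_min"].iloc[k]
        if not np.isfinite(t_true):
            return 0.0
        tau = self.config.transition_sec / 60.0
        return float(np.clip((t_min - t_true) / max(tau, 1e-9), 0.0, 1.0))

    def _cell_crop(self, k: int, m: float) -> np.ndarray:
        """Noiseless brightfield crop of cell k at morph state m."""
        key = (k, round(m, 4))
        if key in self._crop_cache:
            return self._crop_cache[key]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.config.seed, spawn_key=(0, k, 1))
        )
        mask, _ = render_shape_mask(
            self._params[k], self.layout.crop_px, self.layout.pixel_size_um, rng, morph=m
        )
        interior = ndi.binary_erosion(mask, iterations=2)
        crop = np.full((self.layout.crop_px, self.layout.crop_px), _BG)
        crop[mask] = 0.35
        crop[interior] = 0.65
        if len(self._crop_cache) > 4 * len(self._params):
            self._crop_cache.clear()
        self._crop_cache[key] = crop
        return crop

    def frame(self, index: int) -> np.ndarray:
        """Render frame ``index`` (float32 field image)."""
        if not 0 <= index < self.n_frames:
            raise IndexError(f"frame index {index} out of range 0..{self.n_frames - 1}")
        t = self.frame_time_min(index)
        crop = self.layout.crop_px
        canvas = np.full((self.field_px, self.field_px), _BG, dtype=np.float64)
        for k in range(len(self.truth)):
            r0 = (k // self.n_cols) * crop
            c0 = (k % self.n_cols) * crop
            canvas[r0 : r0 + crop, c0 : c0 + crop] = self._cell_crop(k, self._morph_at(k, t))
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.config.seed, spawn_key=(1, index))
        )
        canvas += noise_rng.normal(0.0, _NOISE_SIGMA, canvas.shape)
        return canvas.astype(np.float32)

    def frames(self, indices) -> list[np.ndarray]:
        return [self.frame(int(i)) for i in indices]

    def cell_window(self, frame_img: np.ndarray, k: int) -> np.ndarray:
        crop = self.layout.crop_px
        r0 = (k // self.n_cols) * crop
        c0 = (k % self.n_cols) * crop
        return frame_img[r0 : r0 + crop, c0 : c0 + crop]


def render_video(
    timelines: pd.DataFrame,
    config: KineticsConfig,
    layout: FieldLayout | None = None,
) -> VideoField:
    """Build the lazy video field for a set of ground-truth timelines."""
    return VideoField(timelines, config, layout or FieldLayout())
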