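"""Sampling of imaging-cytometry event populations with ground truth.

The default class mixes emulate a typical imaging-cytometry run:
mostly mature enucleated cells (>95% surface-marker positive, >75%
enucleated), a susceptible fraction converted to crescents/spiculated
forms after chemical deoxygenation, plus the contaminants a real run
contains (nucleated precursors, expelled nuclei, debris, aggregates and
out-of-focus objects).

Per-class counts follow deterministic largest-remainder apportionment of
the configured fractions; event order is then shuffled by the master
seed.  Event ``k`` is reproducible in isolation: its RNG is seeded from
``SeedSequence(entropy=master_seed, spawn_key=(0, k))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shapes import (
    ALL_CLASSES,
    CELL_CLASSES,
    SICKLED_CLASSES,
    ImageEvent,
    ShapeParams,
    render_cell,
)

__all__ = [
    "PopulationConfig",
    "INDUCED_SS_FRACTIONS",
    "INDUCED_TREATED_FRACTIONS",
    "UNINDUCED_FRACTIONS",
    "largest_remainder_counts",
    "sample_population",
    "sample_class_params",
]

#: deoxygenation-induced homozygous-HbS control population
INDUCED_SS_FRACTIONS = {
    "disc": 0.36,
    "sideways": 0.07,
    "crescent": 0.20,
    "star": 0.05,
    "wrinkled": 0.05,
    "spiculated": 0.05,
    "nucleated": 0.14,
    "free_nucleus": 0.045,
    "debris": 0.015,
    "aggregate": 0.02,
}

#: induced population after anti-sickling globin treatment (fewer crescents)
INDUCED_TREATED_FRACTIONS = {
    "disc": 0.41,
    "sideways": 0.07,
    "crescent": 0.16,
    "star": 0.05,
    "wrinkled": 0.05,
    "spiculated": 0.04,
    "nucleated": 0.14,
    "free_nucleus": 0.045,
    "debris": 0.015,
    "aggregate": 0.02,
}

#: uninduced (or non-sickling HbA) population: no crescents
UNINDUCED_FRACTIONS = {
    "disc": 0.59,
    "sideways": 0.10,
    "crescent": 0.0,
    "star": 0.03,
    "wrinkled": 0.06,
    "spiculated": 0.0,
    "nucleated": 0.14,
    "free_nucleus": 0.045,
    "debris": 0.015,
    "aggregate": 0.02,
}


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of one simulated cytometer acquisition."""

    n_events: int = 10000
    class_fractions: dict = field(default_factory=lambda: dict(INDUCED_SS_FRACTIONS))
    marker_positive_fraction: float = 0.97
    defocus_fraction: float = 0.25
    channel_gains: dict = field(default_factory=lambda: {"brightfield": 1.0, "dna": 1.0, "marker": 1.0})
    pixel_size_um: float = 0.5
    crop_px: int = 72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        unknown = set(self.class_fractions) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown shape classes: {sorted(unknown)}")
        if not 0.0 <= self.marker_positive_fraction <= 1.0:
            raise ValueError("marker_positive_fraction must be in [0, 1]")


def largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n among classes.

    Remainder ties are broken alphabetically by class name.
    """
    names = sorted(fractions)
    quotas = np.array([n * fractions[c] for c in names])
    base = np.floor(quotas).astype(int)
    short = n - int(base.sum())
    rema = quotas - base
    order = sorted(range(len(names)), key=lambda i: (-rema[i], names[i]))
    for i in order[:short]:
        base[i] += 1
    return {c: int(k) for c, k in zip(names, base)}


def sample_class_params(shape_class: str, rng: np.random.Generator) -> ShapeParams:
    """Draw population-level shape variability for one event of a class.

    The cellular classes vary in size, mild elongation (orientation /
    tilt in the flow cell) and boundary roughness; crescents vary in
    sickle axis ratio and curvature.  Spread magnitudes were chosen at
    design time so that induced and uninduced feature distributions
    overlap realistically — single-metric Fisher discriminants of order
    1-2 rather than perfect separation, as seen in real imaging
    cytometry of sickling cells.
    """
    size = float(np.clip(rng.normal(8.0, 0.9), 5.5, 10.5))
    orient = rng.uniform(0, np.pi)
    if shape_class == "disc":
        return ShapeParams(
            "disc",
            size_um=size,
            elongation=float(np.clip(1.0 + np.abs(rng.normal(0.0, 0.28)), 1.0, 1.8)),
            noise_amp=rng.uniform(0.02, 0.10),
            orientation_rad=orient,
        )
    if shape_class == "sideways":
        return ShapeParams(
            "sideways",
            size_um=size,
            elongation=float(np.clip(rng.normal(3.2, 0.3), 2.2, 4.2)),
            noise_amp=rng.uniform(0.02, 0.06),
            orientation_rad=orient,
        )
    if shape_class in ("crescent", "spiculated"):
        return ShapeParams(
            shape_class,
            size_um=size,
            elongation=float(np.clip(rng.normal(2.9, 0.25), 2.0, 3.6)),
            curvature=float(np.clip(rng.normal(0.7, 0.12), 0.4, 0.95)),
            noise_amp=rng.uniform(0.02, 0.10),
            n_spicules=int(rng.integers(3, 9)) if shape_class == "spiculated" else 0,
            orientation_rad=orient,
        )
    if shape_class == "star":
        return ShapeParams(
            "star",
            size_um=size,
            harmonic_order=int(rng.integers(4, 8)),
            noise_amp=rng.uniform(0.10, 0.22),
            orientation_rad=orient,
        )
    if shape_class == "wrinkled":
        return ShapeParams(
            "wrinkled",
            size_um=size,
            elongation=float(rng.uniform(1.0, 1.3)),
            noise_amp=rng.uniform(0.10, 0.22),
            orientation_rad=orient,
        )
    if shape_class == "nucleated":
        return ShapeParams(
            "nucleated",
            size_um=float(np.clip(rng.normal(10.0, 0.8), 8.0, 12.5)),
            elongation=float(rng.uniform(1.0, 1.2)),
            noise_amp=rng.uniform(0.02, 0.08),
            orientation_rad=orient,
        )
    if shape_class == "free_nucleus":
        return ShapeParams("free_nucleus", size_um=float(np.clip(rng.normal(3.4, 0.3), 2.6, 4.2)))
    if shape_class == "debris":
        return ShapeParams("debris", size_um=float(rng.uniform(1.2, 2.4)), noise_amp=0.3)
    if shape_class == "aggregate":
        return ShapeParams("aggregate", size_um=size, orientation_rad=orient)
    raise ValueError(f"unknown shape_class {shape_class!r}")


def sample_population(config: PopulationConfig) -> tuple[list[ImageEvent], pd.DataFrame]:
    """Generate a ground-truthed event population.

    Returns the rendered events (shuffled order determined by the seed)
    and an immutable ground-truth table with one row per event:
    class label, marker positivity, defocus status, and whether the
    event is a sickled cell or a mature analysable cell.
    """
    counts = largest_remainder_counts(config.n_events, config.class_fractions)
    labels = np.array(
        [c for c in sorted(counts) for _ in range(counts[c])], dtype=object
    )
    master = np.random.SeedSequence(entropy=config.seed)
    shuffle_rng = np.random.default_rng(master.spawn(1)[0])
    labels = labels[shuffle_rng.permutation(len(labels))]

    events: list[ImageEvent] = []
    rows = []
    for k, cls in enumerate(labels):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(0, k))
        rng = np.random.default_rng(ss)
        params = sample_class_params(cls, rng)
        marker = bool(
            cls in CELL_CLASSES + ("nucleated", "aggregate")
            and rng.random() < config.marker_positive_fraction
        )
        defocused = bool(rng.random() < config.defocus_fraction)
        sigma = rng.uniform(2.5, 4.0) if defocused else rng.uniform(0.0, 0.6)
        from dataclasses import replace

        params = replace(params, defocus_sigma_px=float(sigma))
        eid = f"ev{k:06d}"
        events.append(
            render_cell(
                params,
                seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(0, k, 1)),
                pixel_size_um=config.pixel_size_um,
                crop_px=config.crop_px,
                channel_gains=config.channel_gains,
                marker_positive=marker,
                event_id=eid,
            )
        )
        rows.append(
            {
                "event_id": eid,
                "shape_class": cls,
                "marker_positive": marker,
                "defocused": defocused,
                "sickled": cls in SICKLED_CLASSES,
                "is_mature": (cls in CELL_CLASSES) and marker and not defocused,
                "seed": config.seed,
            }
        )
    truth = pd.DataFrame(rows)
    truth.attrs["seed"] = config.seed
    return events, truth
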