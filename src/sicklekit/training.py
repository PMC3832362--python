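"""Hand-picked-style training sets for metric ranking.

Emulates the selection of unambiguous example cells for statistical
comparison: the "sickle" set contains canonical fully formed crescents
(a tight band of sickle axis ratios, the cells a human would pick as
clear examples), while the "non_sickle" set spans the full range of
uninduced appearances — near-circular discs through moderately
elliptical tilted ones with variable boundary roughness.  Separate
"sideways", "star" and "wrinkled" sets cover the alternative
morphologies.  Each set is rendered, featurised and returned as a
feature table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphometry import featurize_events
from .simulate.population import sample_class_params
from .simulate.shapes import render_cell

__all__ = ["TRAINING_SET_CLASSES", "make_training_sets"]

TRAINING_SET_CLASSES = {
    "sickle": "crescent",
    "non_sickle": "disc",
    "sideways": "sideways",
    "star": "star",
    "wrinkled": "wrinkled",
}


def make_training_sets(
    seed: int = 0,
    n_per_set: int = 200,
    pixel_size_um: float = 0.5,
    crop_px: int = 64,
    sets: tuple[str, ...] = tuple(TRAINING_SET_CLASSES),
) -> dict[str, pd.DataFrame]:
    """Render and featurise labeled training sets (>= 20 events each).

    Events carry the same in-focus imaging variability as the
    population generator (mild defocus jitter, random orientation);
    out-of-focus and contaminant events are excluded, as they would be
    by hand-picking from gated data.
    """
    if n_per_set < 20:
        raise ValueError("each training set needs >= 20 events")
    out: dict[str, pd.DataFrame] = {}
    for s, set_name in enumerate(sets):
        cls = TRAINING_SET_CLASSES[set_name]
        events = []
        for k in range(n_per_set):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(10 + s, k))
            rng = np.random.default_rng(ss)
            params = sample_class_params(cls, rng)
            from dataclasses import replace

            params = replace(params, defocus_sigma_px=float(rng.uniform(0.0, 0.6)))
            events.append(
                render_cell(
                    params,
                    seed=np.random.SeedSequence(entropy=seed, spawn_key=(10 + s, k, 1)),
                    pixel_size_um=pixel_size_um,
                    crop_px=crop_px,
                    event_id=f"{set_name}{k:04d}",
                )
            )
        table = featurize_events(events)
        table = table[~table["degenerate"]].reset_index(drop=True)
        table.attrs["label"] = set_name
        table.attrs["provenance"] = "generator-truth"
        out[set_name] = table
    return out
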