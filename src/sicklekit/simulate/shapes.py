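"""Single-cell image rendering for synthetic imaging-cytometry events.

Renders multi-channel crops (brightfield + DNA stain + surface marker) of
cultured red blood cells in the morphology classes seen after chemical
deoxygenation of HbS-containing cells: biconcave discs seen face-on,
"sideways" (edge-on, non-discoid) cells, elongated sickled crescents,
star-shaped and wrinkled cells, and spiculated crescents with membrane
fibers — plus the contaminant classes an imaging cytometer records
(nucleated precursors, expelled free nuclei, debris, aggregates).

Geometry conventions: pixel grid is 0-based, row-major, origin top-left.
Physical sizes are given in micrometres and converted through
``pixel_size_um``.  Brightfield is transmitted-light-like: bright
background (~0.8 of full scale), dark membrane rim, lighter interior,
with additive Gaussian pixel noise of sigma 2% full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "CELL_CLASSES",
    "SICKLED_CLASSES",
    "ALL_CLASSES",
    "ShapeParams",
    "ImageEvent",
    "render_cell",
    "render_shape_mask",
]

#: morphology classes that are mature (enucleated) cells
CELL_CLASSES = ("disc", "sideways", "crescent", "star", "wrinkled", "spiculated")
#: classes counted as sickled outcomes
SICKLED_CLASSES = ("crescent", "spiculated")
#: contaminants recorded by the cytometer but excluded by gating
CONTAMINANT_CLASSES = ("nucleated", "free_nucleus", "debris", "aggregate")
ALL_CLASSES = CELL_CLASSES + CONTAMINANT_CLASSES

# Brightfield grey levels (fraction of full scale).
_BG = 0.80
_INTERIOR = 0.65
_RIM = 0.35
_NUCLEUS_BF = 0.52
_NOISE_SIGMA = 0.02


@dataclass(frozen=True)
class ShapeParams:
    """Geometric parameters of one rendered object.

    ``size_um`` is the diameter scale of the cell (the diameter of the
    equivalent-area disc).  ``elongation`` is the axis ratio (>= 1):
    for crescents it is the sickle axis ratio, for discs a mild
    out-of-plane tilt, for sideways cells the edge-on projection ratio.
    ``curvature`` in [0, 1] controls how deeply the crescent is cut
    (thinner, more curved sickles at high values).  ``harmonic_order``
    is the number of star points; ``noise_amp`` the boundary-modulation
    amplitude used by star/wrinkled/debris shapes; ``n_spicules`` the
    number of protruding membrane fibers.
    """

    shape_class: str
    size_um: float = 8.0
    elongation: float = 1.0
    curvature: float = 0.7
    harmonic_order: int = 5
    noise_amp: float = 0.0
    n_spicules: int = 0
    defocus_sigma_px: float = 0.0
    orientation_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.shape_class not in ALL_CLASSES:
            raise ValueError(
                f"unknown shape_class {self.shape_class!r}; expected one of {ALL_CLASSES}"
            )
        if self.elongation < 1.0:
            raise ValueError("elongation must be >= 1")
        if not 0.0 <= self.curvature <= 1.0:
            raise ValueError("curvature must be in [0, 1]")
        if self.harmonic_order < 3:
            raise ValueError("harmonic_order must be >= 3")
        if not 0.0 <= self.noise_amp <= 0.5:
            raise ValueError("noise_amp must be in [0, 0.5]")
        if self.n_spicules < 0:
            raise ValueError("n_spicules must be >= 0")
        if self.defocus_sigma_px < 0:
            raise ValueError("defocus_sigma_px must be >= 0")
        if self.size_um <= 0:
            raise ValueError("size_um must be positive")

    @staticmethod
    def for_class(shape_class: str, **overrides) -> "ShapeParams":
        """Canonical parameters for a morphology class.

        These are the fixed reference appearances (e.g. a fully formed
        crescent with axis ratio 3); population-level variability is
        sampled elsewhere.
        """
        defaults = {
            "disc": dict(size_um=8.0),
            "sideways": dict(size_um=8.0, elongation=3.2),
            "crescent": dict(size_um=8.0, elongation=3.0, curvature=0.7),
            "star": dict(size_um=8.0, harmonic_order=5, noise_amp=0.16),
            "wrinkled": dict(size_um=8.0, noise_amp=0.16),
            "spiculated": dict(size_um=8.0, elongation=3.0, curvature=0.7, n_spicules=5),
            "nucleated": dict(size_um=10.0),
            "free_nucleus": dict(size_um=3.4),
            "debris": dict(size_um=2.0, noise_amp=0.3),
            "aggregate": dict(size_um=8.0),
        }
        if shape_class not in defaults:
            raise ValueError(
                f"unknown shape_class {shape_class!r}; expected one of {ALL_CLASSES}"
            )
        kw = defaults[shape_class]
        kw.update(overrides)
        return ShapeParams(shape_class=shape_class, **kw)


@dataclass
class ImageEvent:
    """One multi-channel single-cell image crop — the unit of imaging cytometry."""

    event_id: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    @property
    def crop_px(self) -> int:
        return next(iter(self.channels.values())).shape[0]


def _grid(crop_px: int, orientation: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered, rotated (u, v) coordinate grids in pixels."""
    c = (crop_px - 1) / 2.0
    y, x = np.mgrid[0:crop_px, 0:crop_px].astype(np.float64)
    x -= c
    y -= c
    co, si = np.cos(orientation), np.sin(orientation)
    u = co * x + si * y
    v = -si * x + co * y
    return u, v


def _radial_mask(u, v, r_px, elongation, modulation) -> np.ndarray:
    """Mask of a (possibly elongated) blob with multiplicative boundary modulation.

    The base outline is an area-preserving ellipse with axis ratio
    ``elongation``; ``modulation(theta)`` scales the local radius.
    """
    a = r_px * np.sqrt(elongation)
    b = r_px / np.sqrt(elongation)
    theta = np.arctan2(v / b, u / a)
    r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    mod = modulation(np.arctan2(v, u)) if modulation is not None else 1.0
    rho = np.hypot(u, v)
    return rho <= r_ell * mod


def _crescent_mask(u, v, r_px, elongation, curvature, morph=1.0) -> np.ndarray:
    """Sickled-cell outline: a bent, area-preserved ellipse.

    An ellipse with axis ratio ``elongation`` (axes chosen so its area
    equals the parent disc's — projected area is conserved through
    sickling) is bent by shearing each column of the shape along the
    minor axis by a parabolic offset.  The shear is exactly
    area-preserving and yields the classic curved spindle with tapered
    ends; ``curvature`` scales the bend depth relative to the cell
    thickness.  ``morph`` in [0, 1] interpolates from a disc (0) to the
    fully formed crescent (1); used for the rapid disc->crescent
    transition in time-lapse rendering.
    """
    e_eff = 1.0 + morph * (elongation - 1.0)
    a = r_px * np.sqrt(e_eff)
    b = r_px / np.sqrt(e_eff)
    bend = morph * curvature * 2.2 * b
    vv = v - bend * ((u / a) ** 2 - 0.5)  # -0.5 keeps the centroid near centre
    return (u / a) ** 2 + (vv / b) ** 2 <= 1.0


def _wrinkle_modulation(amp: float, rng: np.random.Generator):
    """Random smooth boundary roughness from harmonics 3..8.

    Orders below 3 are excluded on purpose: wrinkling should not leak
    into the 2-fold symmetry band that the sickle classifier reads.
    """
    orders = np.arange(3, 9)
    amps = rng.normal(0.0, 1.0, orders.size)
    amps /= np.sqrt((amps**2).sum()) + 1e-12
    phases = rng.uniform(0, 2 * np.pi, orders.size)

    def mod(theta):
        s = np.zeros_like(theta)
        for k, a_k, ph in zip(orders, amps, phases):
            s += a_k * np.cos(k * theta + ph)
        return 1.0 + amp * s

    return mod


def _star_modulation(amp: float, order: int, phase: float):
    def mod(theta):
        return 1.0 + amp * np.cos(order * (theta - phase))

    return mod


def _add_spicules(mask, u, v, n, rng: np.random.Generator) -> np.ndarray:
    """Draw 1-2 px wide radial fiber segments protruding from the boundary."""
    out = mask.copy()
    h, w = mask.shape
    c = (h - 1) / 2.0
    rho = np.hypot(u, v)
    for _ in range(n):
        ang = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.sin(ang), np.cos(ang)])  # (row, col) steps
        # walk outward from centre to find the boundary along this ray
        r_b = None
        for r in np.arange(1.0, c, 0.5):
            rr = int(round(c + direction[0] * r))
            cc = int(round(c + direction[1] * r))
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                r_b = r
        if r_b is None:
            continue
        length = rng.uniform(3.0, 7.0)
        wide = rng.random() < 0.5
        for r in np.arange(r_b, min(r_b + length, c - 1), 0.5):
            rr = int(round(c + direction[0] * r))
            cc = int(round(c + direction[1] * r))
            if 0 <= rr < h and 0 <= cc < w:
                out[rr, cc] = True
                if wide and cc + 1 < w:
                    out[rr, cc + 1] = True
    return out


def render_shape_mask(
    params: ShapeParams,
    crop_px: int,
    pixel_size_um: float,
    rng: np.random.Generator,
    morph: float = 1.0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Render the object mask (and nucleus mask if any) for one event.

    Crescent-family masks are rescaled once so that projected area is
    approximately conserved through sickling (cells conserve volume; the
    projected outline elongates and thins rather than shrinking).

    Returns ``(mask, nucleus_mask_or_None)``.
    """
    u, v = _grid(crop_px, params.orientation_rad)
    r_px = (params.size_um / 2.0) / pixel_size_um
    cls = params.shape_class
    nucleus = None

    if cls in ("disc", "sideways", "nucleated"):
        mod = (
            _wrinkle_modulation(params.noise_amp, rng)
            if params.noise_amp > 0
            else None
        )
        mask = _radial_mask(u, v, r_px, params.elongation, mod)
        if cls == "nucleated":
            off = rng.uniform(-0.2, 0.2, 2) * r_px
            nr = 0.45 * r_px
            nucleus = (u - off[0]) ** 2 + (v - off[1]) ** 2 <= nr**2
            nucleus &= mask
    elif cls in ("crescent", "spiculated"):
        mask = _crescent_mask(u, v, r_px, params.elongation, params.curvature, morph)
        if cls == "spiculated" and morph >= 1.0:
            mask = _add_spicules(mask, u, v, params.n_spicules, rng)
    elif cls == "star":
        amp = params.noise_amp if params.noise_amp > 0 else 0.16
        mod = _star_modulation(amp, params.harmonic_order, rng.uniform(0, 2 * np.pi))
        mask = _radial_mask(u, v, r_px, params.elongation, mod)
    elif cls in ("wrinkled", "debris"):
        amp = params.noise_amp if params.noise_amp > 0 else 0.16
        mod = _wrinkle_modulation(amp, rng)
        mask = _radial_mask(u, v, r_px, params.elongation, mod)
    elif cls == "free_nucleus":
        mod = _wrinkle_modulation(0.06, rng)
        mask = _radial_mask(u, v, r_px, 1.0, mod)
        nucleus = mask.copy()
    elif cls == "aggregate":
        # chain of 2-3 touching cells
        n_cells = 2 + int(rng.random() < 0.4)
        off = 0.9 * 2 * r_px
        ang = rng.uniform(0, 2 * np.pi)
        step = np.array([np.cos(ang), np.sin(ang)]) * off
        start = -step * (n_cells - 1) / 2.0
        mask = np.zeros_like(u, dtype=bool)
        for i in range(n_cells):
            cu, cv = start + step * i
            mask |= ((u - cu) ** 2 + (v - cv) ** 2) <= r_px**2
    else:  # pragma: no cover - guarded by ShapeParams validation
        raise ValueError(f"unknown shape_class {cls!r}")
    return mask, nucleus


def _required_crop_px(params: ShapeParams, pixel_size_um: float) -> int:
    r_px = (params.size_um / 2.0) / pixel_size_um
    extent = 2.0 * r_px * np.sqrt(params.elongation) * (1.0 + params.noise_amp)
    if params.shape_class == "aggregate":
        extent = 5.6 * r_px  # up to a 3-cell chain
    if params.n_spicules > 0:
        extent += 14.0
    return int(np.ceil(extent)) + 8


def render_cell(
    params: ShapeParams,
    channels: tuple[str, ...] = ("brightfield", "dna", "marker"),
    seed: int | np.random.SeedSequence = 0,
    *,
    pixel_size_um: float = 0.5,
    crop_px: int = 64,
    channel_gains: dict[str, float] | None = None,
    marker_positive: bool = True,
    event_id: str = "event",
    morph: float = 1.0,
) -> ImageEvent:
    """Render one multi-channel event crop; deterministic for fixed (params, seed).

    Brightfield shows a dark-rimmed object on a bright background.  The
    DNA channel is at background level unless the class carries DNA
    (``nucleated``, ``free_nucleus``).  The marker channel fills the
    membrane area when ``marker_positive``, so its integrated intensity
    scales with mask area.
    """
    if "brightfield" not in channels:
        raise ValueError("channel spec must include 'brightfield'")
    if params.shape_class in ("nucleated", "free_nucleus") and "dna" not in channels:
        raise ValueError(f"{params.shape_class} events require a 'dna' channel")
    need = _required_crop_px(params, pixel_size_um)
    if crop_px < need:
        raise ValueError(
            f"crop_px={crop_px} too small for this shape; use crop_px >= {need}"
        )
    gains = {"brightfield": 1.0, "dna": 1.0, "marker": 1.0}
    if channel_gains:
        gains.update(channel_gains)
    rng = np.random.default_rng(seed)
    mask, nucleus = render_shape_mask(params, crop_px, pixel_size_um, rng)

    faint = params.shape_class in ("free_nucleus", "debris")
    rim_levels = (_RIM, _INTERIOR) if not faint else (0.55, 0.72)
    interior = ndi.binary_erosion(mask, iterations=2)
    bf = np.full((crop_px, crop_px), _BG, dtype=np.float64)
    bf[mask] = rim_levels[0]
    bf[interior] = rim_levels[1]
    if nucleus is not None and params.shape_class == "nucleated":
        bf[nucleus] = _NUCLEUS_BF

    out: dict[str, np.ndarray] = {}
    for ch in channels:
        if ch == "brightfield":
            img = bf * gains["brightfield"]
        elif ch == "dna":
            img = np.full((crop_px, crop_px), 0.001, dtype=np.float64)
            if nucleus is not None:
                img[nucleus] = 1.0 * gains["dna"]
                img = ndi.gaussian_filter(img, 1.0)
        elif ch == "marker":
            img = np.full((crop_px, crop_px), 0.005, dtype=np.float64)
            if marker_positive and params.shape_class not in (
                "free_nucleus",
                "debris",
            ):
                img[mask] = 0.5 * gains["marker"]
                img = ndi.gaussian_filter(img, 0.7)
        else:
            raise ValueError(f"unknown channel {ch!r}")
        if params.defocus_sigma_px > 0:
            img = ndi.gaussian_filter(img, params.defocus_sigma_px)
        sigma = _NOISE_SIGMA if ch == "brightfield" else 0.003
        img = img + rng.normal(0.0, sigma, img.shape)
        out[ch] = img.astype(np.float32)

    meta = {
        "shape_class": params.shape_class,
        "marker_positive": bool(marker_positive),
        "defocus_sigma_px": float(params.defocus_sigma_px),
    }
    return ImageEvent(event_id=event_id, channels=out, pixel_size_um=pixel_size_um, meta=meta)
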