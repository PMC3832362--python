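"""Per-event object masks and shape/texture/intensity morphometry.

Events are single-cell crops (imaging-cytometry convention), so no
crowded-field segmentation is attempted: the object is the largest dark
component of the brightfield crop.

Feature definitions (all lengths in micrometres via ``pixel_size_um``):

* ``length_um`` (L): extent of the mask projected on its major principal
  axis (second-moment eigenvector).
* ``thickness_max_um`` / ``thickness_min_um``: twice the maximum /
  minimum distance-transform value on the medial axis.  For the minimum,
  skeleton side-branches shorter than 10% of L are pruned and the
  terminal 10% of the remaining path is excluded, because unpruned
  medial-axis tips taper to zero thickness on every shape.
* ``shape_ratio``: Tmin / L — low for elongated (sickled) cells.
* ``symmetry2``: |c2| / |c0| of the boundary radius function r(theta)
  sampled at 256 angles about the centroid (max radius per angle) —
  high for cells with strong 2-fold symmetry, i.e. elongated cells.
* ``h_contrast`` / ``h_entropy``: grey-level co-occurrence contrast and
  entropy (bits) inside the mask, 16 grey levels, offset 1 px.
* ``focus_score``: RMS gradient magnitude normalised by mean intensity.
* ``sickle_score``: symmetry2 / shape_ratio — the sickling classifier.

Degenerate events (blank crops, masks below 16 px) yield a flagged
record with features absent (NaN), never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .simulate.shapes import ImageEvent

__all__ = [
    "ObjectMask",
    "segment_event",
    "shape_features",
    "symmetry2",
    "texture_features",
    "focus_score",
    "featurize",
    "featurize_events",
    "SHAPE_RATIO_EPS",
    "FEATURE_COLUMNS",
]

#: discretization slack on shape_ratio / thickness inequalities
SHAPE_RATIO_EPS = 0.05
_MIN_AREA_PX = 16
_N_ANGLES = 256
_GLCM_LEVELS = 16


@dataclass
class ObjectMask:
    """Binary object mask with its source channel; may be degenerate."""

    mask: np.ndarray | None
    channel: str
    degenerate: bool = False
    reason: str = ""

    @property
    def area_px(self) -> int:
        return 0 if self.mask is None else int(self.mask.sum())


def segment_event(event: ImageEvent, channel: str = "brightfield") -> ObjectMask:
    """Threshold the (inverted) brightfield crop into a single object mask.

    Automatic bimodal (Otsu) threshold on the inverted channel, hole
    filling, one binary closing, largest connected component.  A crop
    whose foreground/background separation is within the noise floor is
    flagged degenerate rather than raising.
    """
    if channel not in event.channels:
        raise ValueError(f"channel {channel!r} not present in event {event.event_id}")
    img = np.asarray(event.channels[channel], dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty crop")
    inv = img.max() - img
    thr = threshold_otsu(inv)
    fg = inv > thr
    if not fg.any() or fg.all():
        return ObjectMask(None, channel, True, "no foreground after thresholding")
    # blank crops: Otsu splits pure noise; require real contrast between sides
    if inv[fg].mean() - inv[~fg].mean() < 0.06:
        return ObjectMask(None, channel, True, "no foreground after thresholding")
    fg = ndi.binary_fill_holes(fg)
    fg = ndi.binary_closing(fg, structure=np.ones((3, 3), bool))
    fg = ndi.binary_fill_holes(fg)
    lab, n = ndi.label(fg)
    if n == 0:
        return ObjectMask(None, channel, True, "no foreground after thresholding")
    sizes = ndi.sum_labels(fg, lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = lab == keep
    if mask.sum() < _MIN_AREA_PX:
        return ObjectMask(None, channel, True, f"mask area {int(mask.sum())} px < {_MIN_AREA_PX}")
    return ObjectMask(mask, channel)


# ---------------------------------------------------------------------------
# skeleton utilities

_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    pts = set(zip(*np.nonzero(skel)))
    adj = {
        p: [q for d in _NBR if (q := (p[0] + d[0], p[1] + d[1])) in pts] for p in pts
    }
    return pts, adj


def _step(p, q) -> float:
    return 1.0 if (p[0] == q[0] or p[1] == q[1]) else np.sqrt(2.0)


def _prune_branches(pts, adj, max_len: float, dist: np.ndarray):
    """Iteratively remove spurious endpoint-to-junction side branches.

    A branch is pruned when it terminates at a junction and is shorter
    than ``max_len`` (10% of the object length) or than 1.5x the
    inscribed radius at its junction — the latter removes skeleton
    spurs (corner artifacts, boundary-wrinkle spurs) that barely leave
    the maximal disk of the junction they sprout from.
    """
    pts = set(pts)
    changed = True
    while changed:
        changed = False
        endpoints = [p for p in pts if len([q for q in adj[p] if q in pts]) == 1]
        for ep in endpoints:
            if ep not in pts:
                continue
            branch = [ep]
            length = 0.0
            cur, prev = ep, None
            junction = None
            while True:
                nbrs = [q for q in adj[cur] if q in pts and q != prev]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                deg = len([q for q in adj[nxt] if q in pts])
                length += _step(cur, nxt)
                if deg > 2:  # reached a junction: branch ends before it
                    junction = nxt
                    break
                branch.append(nxt)
                prev, cur = cur, nxt
            if junction is None:
                continue  # whole-skeleton path, not a side branch
            limit = max(max_len, 1.5 * float(dist[junction]))
            if length < limit and len(branch) < len(pts):
                pts -= set(branch)
                changed = True
    return pts


def _geodesic_from_endpoints(pts, adj):
    """Multi-source Dijkstra distance (8-connected, sqrt(2) diagonals)."""
    import heapq

    endpoints = [p for p in pts if len([q for q in adj[p] if q in pts]) == 1]
    if not endpoints:  # loop or single point: no terminal region
        return {p: np.inf for p in pts}, 0.0
    dist = {p: np.inf for p in pts}
    heap = []
    for ep in endpoints:
        dist[ep] = 0.0
        heapq.heappush(heap, (0.0, ep))
    while heap:
        d, p = heapq.heappop(heap)
        if d > dist[p]:
            continue
        for q in adj[p]:
            if q in dist:
                nd = d + _step(p, q)
                if nd < dist[q]:
                    dist[q] = nd
                    heapq.heappush(heap, (nd, q))
    total = 0.0
    for p in pts:
        for q in adj[p]:
            if q in dist:
                total += _step(p, q)
    total /= 2.0  # each edge counted twice
    return dist, total


def _principal_extents(mask: np.ndarray) -> tuple[float, float, np.ndarray]:
    ys, xs = np.nonzero(mask)
    coords = np.column_stack([xs, ys]).astype(np.float64)
    coords -= coords.mean(axis=0)
    cov = np.cov(coords.T) if len(coords) > 1 else np.eye(2)
    w, vecs = np.linalg.eigh(cov)
    major = vecs[:, np.argmax(w)]
    minor = vecs[:, np.argmin(w)]
    p1 = coords @ major
    p2 = coords @ minor
    return float(np.ptp(p1)) + 1.0, float(np.ptp(p2)) + 1.0, major


def shape_features(obj: ObjectMask, pixel_size_um: float) -> dict[str, float]:
    """Length, thicknesses, shape ratio, aspect ratio, circularity, area.

    Raises ``ValueError`` on a degenerate mask; callers batching events
    should check ``obj.degenerate`` first.
    """
    if obj.degenerate or obj.mask is None:
        raise ValueError("degenerate mask has no shape features")
    mask = obj.mask
    L_px, W_px, _ = _principal_extents(mask)
    dist = ndi.distance_transform_edt(mask)
    on = skeletonize(mask) & mask
    if not on.any():
        raise ValueError("empty medial axis")
    tmax_px = 2.0 * float(dist[mask].max())  # attained on the medial axis

    pts, adj = _skeleton_graph(on)
    kept = _prune_branches(pts, adj, 0.10 * L_px, dist)
    if not kept:
        kept = pts
    gdist, total_len = _geodesic_from_endpoints(kept, adj)
    if total_len > 0:
        retained = {p for p in kept if gdist[p] >= 0.10 * total_len}
        if not retained:
            retained = kept
    else:
        retained = kept
    tmin_px = 2.0 * min(dist[p] for p in retained)
    tmin_px = min(tmin_px, tmax_px)

    area_px = float(mask.sum())
    perim_px = float(measure.perimeter(mask, neighborhood=4))
    circ = 4.0 * np.pi * area_px / perim_px**2 if perim_px > 0 else np.nan
    circ = min(circ, 1.0)

    L = L_px * pixel_size_um
    shape_ratio = float(np.clip(tmin_px / L_px, 1e-6, 1.0 + SHAPE_RATIO_EPS))
    return {
        "area_um2": area_px * pixel_size_um**2,
        "length_um": L,
        "thickness_min_um": tmin_px * pixel_size_um,
        "thickness_max_um": tmax_px * pixel_size_um,
        "shape_ratio": shape_ratio,
        "aspect_ratio": float(L_px / W_px) if W_px > 0 else np.nan,
        "circularity": float(circ),
    }


def _boundary_radii(mask: np.ndarray, n_angles: int = _N_ANGLES) -> np.ndarray:
    """r(theta) at n uniform angles about the centroid.

    The sub-pixel boundary polygon (marching squares at level 0.5) is
    intersected with each ray; the maximum intersection distance is
    taken, so multi-valued boundaries (concave outlines) use their outer
    radius.  Angles whose ray never crosses the boundary get r = 0.
    """
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary contour")
    segs = []
    for cont in contours:
        a = cont
        b = np.roll(cont, -1, axis=0)
        segs.append(np.concatenate([a, b], axis=1))  # (y0,x0,y1,x1)
    S = np.concatenate(segs, axis=0)
    y0, x0, y1, x1 = (S[:, 0] - cy, S[:, 1] - cx, S[:, 2] - cy, S[:, 3] - cx)

    theta = np.arange(n_angles) * (2 * np.pi / n_angles)
    dx, dy = np.cos(theta), np.sin(theta)
    # solve r*(dx,dy) = p0 + t*(p1-p0) for each (ray, segment) pair (Cramer)
    ex, ey = (x1 - x0), (y1 - y0)
    D = ex[None, :] * dy[:, None] - ey[None, :] * dx[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ex[None, :] * y0[None, :] - ey[None, :] * x0[None, :]) / D
        t = (dx[:, None] * y0[None, :] - dy[:, None] * x0[None, :]) / D
    valid = (t >= 0.0) & (t <= 1.0) & (r > 0) & np.isfinite(r)
    r = np.where(valid, r, 0.0)
    return r.max(axis=1)


def symmetry2(obj: ObjectMask) -> float:
    """2-fold symmetry: |c2|/|c0| of the boundary radius function."""
    if obj.degenerate or obj.mask is None:
        raise ValueError("degenerate mask has no symmetry")
    radii = _boundary_radii(obj.mask)
    coeffs = np.fft.fft(radii)
    c0 = np.abs(coeffs[0])
    if c0 == 0:
        return 0.0
    return float(np.clip(np.abs(coeffs[2]) / c0, 0.0, 1.0))


def texture_features(
    event: ImageEvent, obj: ObjectMask, channel: str = "brightfield"
) -> tuple[float, float]:
    """Grey-level co-occurrence contrast and entropy inside the mask.

    Intensities inside the mask are quantised to 16 grey levels
    (min-max); co-occurrences at the four axis-aligned 1 px offsets are
    pooled, symmetrised and normalised.  A constant interior gives
    (0, 0).
    """
    if obj.degenerate or obj.mask is None:
        raise ValueError("degenerate mask has no texture")
    if channel not in event.channels:
        raise ValueError(f"channel {channel!r} not present")
    img = np.asarray(event.channels[channel], dtype=np.float64)
    mask = obj.mask
    vals = img[mask]
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return 0.0, 0.0
    q = np.zeros_like(img, dtype=np.int64)
    q[mask] = np.minimum(
        ((img[mask] - vmin) / (vmax - vmin) * _GLCM_LEVELS).astype(np.int64),
        _GLCM_LEVELS - 1,
    )
    glcm = np.zeros((_GLCM_LEVELS, _GLCM_LEVELS), dtype=np.float64)
    for dy, dx in ((0, 1), (1, 0), (0, -1), (-1, 0)):
        a = mask[max(dy, 0) or None : min(dy, 0) or None, max(dx, 0) or None : min(dx, 0) or None]
        b = mask[max(-dy, 0) or None : min(-dy, 0) or None, max(-dx, 0) or None : min(-dx, 0) or None]
        qa = q[max(dy, 0) or None : min(dy, 0) or None, max(dx, 0) or None : min(dx, 0) or None]
        qb = q[max(-dy, 0) or None : min(-dy, 0) or None, max(-dx, 0) or None : min(-dx, 0) or None]
        both = a & b
        np.add.at(glcm, (qa[both], qb[both]), 1.0)
    glcm = glcm + glcm.T
    total = glcm.sum()
    if total == 0:
        return 0.0, 0.0
    P = glcm / total
    i, j = np.meshgrid(np.arange(_GLCM_LEVELS), np.arange(_GLCM_LEVELS), indexing="ij")
    contrast = float((P * (i - j) ** 2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return contrast, entropy


def focus_score(event: ImageEvent, channel: str = "brightfield") -> float:
    """Sharpness: RMS gradient magnitude over the crop / mean intensity."""
    if channel not in event.channels:
        raise ValueError(f"channel {channel!r} not present")
    img = np.asarray(event.channels[channel], dtype=np.float64)
    mean = img.mean()
    if mean <= 0:
        raise ValueError("zero-intensity crop")
    gy, gx = np.gradient(img)
    return float(np.sqrt(np.mean(gx**2 + gy**2)) / mean)


FEATURE_COLUMNS = [
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
    "sickle_score",
]


def featurize(event: ImageEvent) -> dict:
    """Full feature record for one event (flagged if degenerate).

    Always includes per-channel mean and integrated intensities and the
    focus score (computed on the raw crop, mask-free); mask-based
    features are NaN when the mask is degenerate.
    """
    if "brightfield" not in event.channels:
        raise ValueError("event lacks a brightfield channel")
    rec: dict = {"event_id": event.event_id, "degenerate": False, "flag_reason": ""}
    for ch, img in event.channels.items():
        arr = np.asarray(img, dtype=np.float64)
        rec[f"mean_{ch}"] = float(arr.mean())
        rec[f"integrated_{ch}"] = float(arr.sum())
    rec["focus_score"] = focus_score(event)
    obj = segment_event(event)
    if obj.degenerate:
        rec["degenerate"] = True
        rec["flag_reason"] = obj.reason
        for col in FEATURE_COLUMNS:
            rec.setdefault(col, np.nan)
        return rec
    try:
        rec.update(shape_features(obj, event.pixel_size_um))
        rec["symmetry2"] = symmetry2(obj)
    except ValueError as exc:
        rec["degenerate"] = True
        rec["flag_reason"] = str(exc)
        for col in FEATURE_COLUMNS:
            rec.setdefault(col, np.nan)
        return rec
    rec["h_contrast"], rec["h_entropy"] = texture_features(event, obj)
    rec["sickle_score"] = (
        rec["symmetry2"] / rec["shape_ratio"] if rec["shape_ratio"] > 0 else np.nan
    )
    return rec


def featurize_events(events) -> pd.DataFrame:
    """Feature table with one row per event and a degenerate flag column."""
    return pd.DataFrame([featurize(ev) for ev in events])
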