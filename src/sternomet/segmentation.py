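"""Silhouette segmentation of a single bone from a 2D grayscale projection.

The segmentation phase recovers a closed border contour of the manubrium or
sternal body from a bright-bone-on-dark-background image in five steps:

1. adaptive thresholding on local areas,
2. topological-potential filtering of border-pixel candidates,
3. structural connection modelling (bridging breaks between border chains),
4. border contour reconstruction (closed chains -> polygons with features),
5. classification of contours by bone-like feature bounds.

All stages are deterministic given the image and the parameters.  Points are
(x, y) = (column, row) pairs in pixel units, origin at the top-left pixel
center, y increasing downward; geometry is kept in floats at sub-pixel
precision.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "BoneImage",
    "SegmentationParams",
    "Chain",
    "Contour",
    "SegmentationError",
    "adaptive_threshold",
    "filter_border_candidates",
    "connect_breaks",
    "trace_contours",
    "classify_contours",
    "segment_bone",
]

logger = logging.getLogger(__name__)

BONE_KINDS = ("manubrium", "corpus", "unknown")


class SegmentationError(RuntimeError):
    """Raised when no acceptable bone contour can be recovered.

    Carries the name of the last pipeline stage that still produced output.
    """

    def __init__(self, message: str, last_stage: str | None = None):
        super().__init__(message)
        self.last_stage = last_stage


@dataclass
class BoneImage:
    """A 2D grayscale bone projection with physical pixel spacing.

    Parameters
    ----------
    pixels : 2D float array of intensities.
    spacing : physical size of one pixel in cm.
    kind : "manubrium", "corpus" or "unknown".
    ident : free-form identifier (e.g. subject id).
    """

    pixels: np.ndarray
    spacing: float
    kind: str = "unknown"
    ident: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("BoneImage.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("BoneImage.pixels must be finite")
        if not self.spacing > 0:
            raise ValueError(f"pixel spacing must be > 0, got {self.spacing}")
        if self.kind not in BONE_KINDS:
            raise ValueError(f"unknown bone kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation phase.

    window : side of the square local-mean window (odd, >= 3), px.
    offset : intensity added to the local mean to form the threshold.
    potential_scale : Gaussian kernel scale (sigma, px) of the border-density
        potential.
    potential_threshold : minimum potential for a border pixel to survive.
    max_gap : largest endpoint gap (px) the bridge step will close.
    tangent_cos : minimum cosine between chain end tangents and the bridge
        direction for a bridge to be admissible.
    min_area..min_solidity : contour-classifier feature bounds.
    """

    window: int = 151
    offset: float = 80.0
    potential_scale: float = 2.0
    potential_threshold: float = 2.5
    max_gap: float = 12.0
    tangent_cos: float = 0.5
    min_area: float = 2000.0
    max_area: float = 80000.0
    min_interior_intensity: float = 500.0
    max_elongation: float = 8.0
    min_solidity: float = 0.60

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_area > self.max_area:
            raise ValueError("min_area must be <= max_area")
        if self.potential_scale <= 0:
            raise ValueError("potential_scale must be > 0")


@dataclass
class Chain:
    """An ordered chain of border pixels; closed when it forms a cycle."""

    points: np.ndarray  # (N, 2) float, (x, y)
    closed: bool = False

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Contour:
    """A closed border polygon with quality features.

    ``points`` is closed (first point repeated at the end).  Features follow
    standard definitions: shoelace area, polygon centroid, perimeter, mean
    intensity of the rasterized interior, elongation = major/minor axis ratio,
    solidity = area / convex-hull area.
    """

    points: np.ndarray
    centroid: tuple[float, float]
    area: float
    perimeter: float
    mean_interior_intensity: float
    elongation: float
    solidity: float
    accepted: Optional[bool] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if len(pts) < 4 or not np.allclose(pts[0], pts[-1]):
            raise ValueError("Contour.points must be closed with >= 3 vertices")
        self.points = pts
        if not self.area > 0:
            raise ValueError("Contour area must be > 0")


# ---------------------------------------------------------------------------
# stage 1: adaptive threshold
# ---------------------------------------------------------------------------

def adaptive_threshold(image: BoneImage, params: SegmentationParams) -> np.ndarray:
    """Binary mask: pixel is foreground iff intensity > local mean + offset.

    The local mean is taken over a ``window`` x ``window`` square with
    reflected boundaries.  Raises if the window does not fit in the image.
    """
    h, w = image.shape
    if params.window > min(h, w):
        raise ValueError(
            f"local window {params.window} exceeds image extent {image.shape}"
        )
    local_mean = ndimage.uniform_filter(image.pixels, size=params.window, mode="reflect")
    return image.pixels > local_mean + params.offset


# ---------------------------------------------------------------------------
# stage 2: border extraction + topological potential filtering
# ---------------------------------------------------------------------------

def _border_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (image border counts as bg)."""
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return mask & ~interior


def border_potential(coords: np.ndarray, scale: float,
                     shape: tuple[int, int] | None = None) -> np.ndarray:
    """Topological potential of each border pixel.

    p_i = sum_j exp(-|x_i - x_j|^2 / (2 scale^2)) over all border pixels j
    (including i itself).  Exact pairwise evaluation for small border sets;
    for large sets a separable truncated convolution (radius 5 sigma) whose
    omitted tail is < 4e-6 per pixel.
    """
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    if n <= 6000:
        d2 = cdist(coords, coords, "sqeuclidean")
        return np.exp(-d2 / (2.0 * scale**2)).sum(axis=1)
    # large sets: convolve an indicator image with the (unnormalized) kernel
    assert shape is not None
    ind = np.zeros(shape)
    ind[coords[:, 1].astype(int), coords[:, 0].astype(int)] = 1.0
    r = int(np.ceil(5 * scale))
    k1 = np.exp(-np.arange(-r, r + 1) ** 2 / (2.0 * scale**2))
    tmp = ndimage.convolve1d(ind, k1, axis=0, mode="constant")
    tmp = ndimage.convolve1d(tmp, k1, axis=1, mode="constant")
    return tmp[coords[:, 1].astype(int), coords[:, 0].astype(int)]


def _order_component(coords: np.ndarray) -> tuple[np.ndarray, bool]:
    """Order the pixels of one 8-connected border component into a chain.

    A component that contains a cycle (edge count >= node count in its
    8-adjacency graph) is a closed border loop: its dangling spurs are
    pruned and the remaining cycle is walked.  Acyclic components are open
    chains walked endpoint to endpoint.
    """
    pts = [tuple(p) for p in coords]
    ptset = set(pts)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def neighbors(p):
        return [(p[0] + dx, p[1] + dy) for dx, dy in offsets if (p[0] + dx, p[1] + dy) in ptset]

    degree = {p: len(neighbors(p)) for p in pts}
    has_cycle = sum(degree.values()) // 2 >= len(pts)
    if has_cycle:
        # prune spurs until only the cycle (plus thick clusters) remains
        leaves = [p for p in pts if degree[p] <= 1]
        while leaves and len(ptset) > 3:
            for p in leaves:
                if p in ptset and degree.get(p, 0) <= 1:
                    ptset.discard(p)
                    for q in neighbors(p):
                        degree[q] -= 1
            leaves = [p for p in ptset if degree.get(p, 0) <= 1]
        pts = [p for p in pts if p in ptset]
        start = min(pts)
    else:
        endpoints = [p for p in pts if degree[p] <= 1]
        start = min(endpoints) if endpoints else min(pts)

    visited = {start}
    order = [start]
    cur = start
    prev_dir = None
    while len(visited) < len(pts):
        cand = [q for q in neighbors(cur) if q not in visited]
        if not cand:
            # thick junctions can strand pixels; pick them up only when they
            # are adjacent to the current path head, otherwise drop them
            rest = [p for p in pts if p not in visited]
            near = min(rest, key=lambda q: (q[0] - cur[0]) ** 2 + (q[1] - cur[1]) ** 2)
            if (near[0] - cur[0]) ** 2 + (near[1] - cur[1]) ** 2 > 8:
                break
            cand = [near]
        if prev_dir is not None and len(cand) > 1:
            # prefer continuing in the same direction
            cand.sort(key=lambda q: -(
                (q[0] - cur[0]) * prev_dir[0] + (q[1] - cur[1]) * prev_dir[1]
            ))
        else:
            # prefer 4-neighbours over diagonals
            cand.sort(key=lambda q: abs(q[0] - cur[0]) + abs(q[1] - cur[1]))
        nxt = cand[0]
        prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
        visited.add(nxt)
        order.append(nxt)
        cur = nxt
    arr = np.asarray(order, dtype=float)
    return arr, has_cycle and len(arr) >= 4


def filter_border_pixels(mask: np.ndarray,
                         params: SegmentationParams) -> np.ndarray:
    """Border pixels (x, y) whose topological potential passes the threshold."""
    border = _border_mask(np.asarray(mask, dtype=bool))
    ys, xs = np.nonzero(border)
    if len(xs) == 0:
        return np.empty((0, 2), dtype=int)
    coords = np.column_stack([xs, ys]).astype(float)
    pot = border_potential(coords, params.potential_scale, shape=mask.shape)
    keep = pot >= params.potential_threshold
    return np.column_stack([xs[keep], ys[keep]])


def filter_border_candidates(mask: np.ndarray, params: SegmentationParams) -> list[Chain]:
    """Extract border pixels, drop low-potential ones, group into chains."""
    kept = filter_border_pixels(mask, params)
    if len(kept) == 0:
        return []
    surviving = np.zeros(np.asarray(mask).shape, dtype=bool)
    surviving[kept[:, 1], kept[:, 0]] = True
    labels, n = ndimage.label(surviving, structure=np.ones((3, 3), dtype=int))
    chains = []
    for lab in range(1, n + 1):
        lys, lxs = np.nonzero(labels == lab)
        comp = np.column_stack([lxs, lys])
        if len(comp) == 1:
            chains.append(Chain(points=comp.astype(float), closed=False))
            continue
        pts, closed = _order_component(comp)
        chains.append(Chain(points=pts, closed=closed))
    return chains


# ---------------------------------------------------------------------------
# stage 3: structural connection modelling (break bridging)
# ---------------------------------------------------------------------------

def _end_tangent(chain: Chain, end: int) -> np.ndarray:
    """Outward tangent direction at a chain end (0 = first point, 1 = last)."""
    pts = chain.points
    k = min(5, len(pts) - 1)
    if end == 0:
        v = pts[0] - pts[k]
    else:
        v = pts[-1] - pts[-1 - k]
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros(2)


def connect_breaks(chains: Sequence[Chain], params: SegmentationParams) -> list[Chain]:
    """Bridge compatible open-chain endpoints, nearest pair first.

    Two endpoints may be joined when their gap is <= ``max_gap`` and the
    bridge direction is tangent-compatible with both chain ends
    (cosine >= ``tangent_cos``).  Each endpoint is used at most once; a chain
    may close onto itself.  Existing chain points are never moved.
    """
    chains = [Chain(points=c.points.copy(), closed=c.closed) for c in chains]
    open_idx = [i for i, c in enumerate(chains) if not c.closed and len(c) >= 2]
    # endpoints: (chain index, end flag)
    ends = [(i, e) for i in open_idx for e in (0, 1)]
    pos = {(i, e): chains[i].points[0 if e == 0 else -1] for (i, e) in ends}
    tang = {(i, e): _end_tangent(chains[i], e) for (i, e) in ends}

    candidates = []
    for a in range(len(ends)):
        for b in range(a + 1, len(ends)):
            ea, eb = ends[a], ends[b]
            if ea[0] == eb[0] and len(chains[ea[0]]) < 3:
                continue
            gap = float(np.linalg.norm(pos[ea] - pos[eb]))
            if gap > params.max_gap:
                continue
            if gap > 1e-9:
                u = (pos[eb] - pos[ea]) / gap
                if np.dot(tang[ea], u) < params.tangent_cos:
                    continue
                if np.dot(tang[eb], -u) < params.tangent_cos:
                    continue
            candidates.append((gap, ea, eb))
    candidates.sort(key=lambda t: t[0])

    used: set[tuple[int, int]] = set()
    bridges = []
    for gap, ea, eb in candidates:
        if ea in used or eb in used:
            continue
        used.add(ea)
        used.add(eb)
        bridges.append((ea, eb))

    # assemble merged chains; map original endpoint -> (current record, end)
    records = {i: {"points": chains[i].points, "ends": {0: (i, 0), 1: (i, 1)}}
               for i in open_idx}
    where = {(i, e): (i, e) for (i, e) in ends}  # original endpoint -> (record key, side)
    closed_flags = {i: False for i in open_idx}

    def bridge_pts(p, q):
        gap = np.linalg.norm(q - p)
        n = int(np.ceil(gap))
        if n <= 1:
            return np.empty((0, 2))
        ts = np.linspace(0, 1, n + 1)[1:-1]
        return p[None, :] + ts[:, None] * (q - p)[None, :]

    for ea, eb in bridges:
        ka, sa = where[ea]
        kb, sb = where[eb]
        if ka == kb:
            # close the chain onto itself
            rec = records[ka]
            p, q = rec["points"][-1], rec["points"][0]
            rec["points"] = np.vstack([rec["points"], bridge_pts(p, q)])
            closed_flags[ka] = True
            continue
        ra, rb = records[ka], records[kb]
        apts = ra["points"] if sa == 1 else ra["points"][::-1]
        a_other = ra["ends"][0 if sa == 1 else 1]
        bpts = rb["points"] if sb == 0 else rb["points"][::-1]
        b_other = rb["ends"][1 if sb == 0 else 0]
        merged = np.vstack([apts, bridge_pts(apts[-1], bpts[0]), bpts])
        records[ka] = {"points": merged, "ends": {0: a_other, 1: b_other}}
        del records[kb]
        where[a_other] = (ka, 0)
        where[b_other] = (ka, 1)
        closed_flags[ka] = closed_flags.get(ka, False) or closed_flags.pop(kb, False)

    out = [c for c in chains if c.closed]
    for k, rec in records.items():
        out.append(Chain(points=rec["points"], closed=closed_flags[k]))
    return out


# ---------------------------------------------------------------------------
# stage 4: contour reconstruction
# ---------------------------------------------------------------------------

def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def _polygon_centroid(pts: np.ndarray, signed_area: float) -> tuple[float, float]:
    if abs(signed_area) < 1e-12:
        return tuple(pts[:-1].mean(axis=0))
    x, y = pts[:, 0], pts[:, 1]
    cross = x[:-1] * y[1:] - x[1:] * y[:-1]
    cx = np.sum((x[:-1] + x[1:]) * cross) / (6.0 * signed_area)
    cy = np.sum((y[:-1] + y[1:]) * cross) / (6.0 * signed_area)
    return float(cx), float(cy)


def rasterize_polygon(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose centers lie inside the polygon."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask


def trace_contours(chains: Sequence[Chain],
                   image: BoneImage | None = None) -> list[Contour]:
    """Turn closed chains into Contour objects; open chains are discarded."""
    contours = []
    dropped = 0
    for chain in chains:
        if not chain.closed or len(chain) < 3:
            dropped += 1
            continue
        pts = chain.points
        if not np.allclose(pts[0], pts[-1]):
            pts = np.vstack([pts, pts[0]])
        signed = _shoelace(pts)
        area = abs(signed)
        if area <= 0:
            dropped += 1
            continue
        centroid = _polygon_centroid(pts, signed)
        perimeter = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        interior_mean = float("nan")
        elong, solidity = 1.0, 1.0
        shape = image.shape if image is not None else (
            int(np.ceil(pts[:, 1].max())) + 2, int(np.ceil(pts[:, 0].max())) + 2)
        mask = rasterize_polygon(pts, shape)
        if mask.any():
            if image is not None:
                interior_mean = float(image.pixels[mask].mean())
            props = regionprops(sk_label(mask))
            props = max(props, key=lambda p: p.area)
            minor = props.axis_minor_length
            elong = float(props.axis_major_length / minor) if minor > 0 else float("inf")
            solidity = float(props.solidity)
        contours.append(Contour(
            points=pts, centroid=centroid, area=area, perimeter=perimeter,
            mean_interior_intensity=interior_mean, elongation=elong,
            solidity=solidity))
    if dropped:
        logger.info("trace_contours: discarded %d open/degenerate chains", dropped)
    return contours


# ---------------------------------------------------------------------------
# stage 5: classification
# ---------------------------------------------------------------------------

def classify_contours(contours: Sequence[Contour], image: BoneImage,
                      params: SegmentationParams) -> list[Contour]:
    """Accept contours whose every quality feature lies inside the bounds."""
    accepted = []
    for c in contours:
        intensity = c.mean_interior_intensity
        if np.isnan(intensity):
            mask = rasterize_polygon(c.points, image.shape)
            intensity = float(image.pixels[mask].mean()) if mask.any() else -np.inf
            c.mean_interior_intensity = intensity
        ok = (
            params.min_area <= c.area <= params.max_area
            and intensity >= params.min_interior_intensity
            and c.elongation <= params.max_elongation
            and c.solidity >= params.min_solidity
        )
        c.accepted = bool(ok)
        if ok:
            accepted.append(c)
    return accepted


# ---------------------------------------------------------------------------
# full segmentation
# ---------------------------------------------------------------------------

def segment_bone(image: BoneImage,
                 params: SegmentationParams | None = None) -> Contour:
    """Compose the five stages and return the best accepted contour.

    Among accepted contours the largest area wins; ties fall to higher mean
    interior intensity, then to the smaller centroid row.
    """
    params = params or SegmentationParams()
    mask = adaptive_threshold(image, params)
    if not mask.any():
        raise SegmentationError(
            "no foreground pixels (last non-empty stage: input image)",
            last_stage="adaptive_threshold")
    chains = filter_border_candidates(mask, params)
    if not chains:
        raise SegmentationError(
            "no border chains survive potential filtering "
            "(last non-empty stage: adaptive_threshold)",
            last_stage="filter_border_candidates")
    chains = connect_breaks(chains, params)
    contours = trace_contours(chains, image)
    if not contours:
        raise SegmentationError(
            "no closed contours (last non-empty stage: connect_breaks)",
            last_stage="trace_contours")
    accepted = classify_contours(contours, image, params)
    if not accepted:
        raise SegmentationError(
            "no contour passes bone-feature classification "
            "(last non-empty stage: trace_contours)",
            last_stage="classify_contours")
    return max(accepted, key=lambda c: (
        c.area, c.mean_interior_intensity, -c.centroid[1]))
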