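"""Landmark configuration and osteometric measurement on a bone contour.

Given an accepted silhouette contour, this module locates the anatomical
landmarks of the five standard sternal measurements and converts landmark
geometry into centimeters:

* ``M``    manubrium length: midpoint between the jugular and clavicular
           notches down to the manubriosternal junction (operationalized as
           the inferior midline extreme of the manubrium silhouette).
* ``MW``   manubrium width: chord at the level of the line through the left
           and right costal notch 1 midpoints.
* ``B``    sternal body length: manubriosternal junction (superior midline
           extreme) to the mesoxiphoid junction (inferior midline extreme).
* ``CSW1`` body width at the line through the costal notch 2/3 midpoints.
* ``CSW2`` body width at the line through the costal notch 4/5 midpoints.

The contour is resampled to uniform arc length, smoothed, and split into
anatomical sections by its symmetry midline; notches are local extrema of
the lateral indentation profile ("algorithm of local extremes and in
sections").  Width section lines are clipped to the contour polygon, so a
width is always a chord length.  A candidate-reduction step (1-D
single-linkage clustering with best-candidate selection) and a grid-search
training loop for the segmentation parameters complete the measurement
phase.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from shapely.geometry import LineString, Polygon

from .segmentation import (BoneImage, Contour, SegmentationError,
                           SegmentationParams, segment_bone)

__all__ = [
    "LandmarkParams",
    "LandmarkConfiguration",
    "MeasurementRecord",
    "IndexRecord",
    "TrainingResult",
    "MeasurementError",
    "PIPELINE_LANDMARK_PARAMS",
    "find_landmarks",
    "cluster_candidates",
    "measure_bone",
    "compute_indices",
    "tune_parameters",
    "default_parameter_grid",
    "measure_image",
]

MANUBRIUM_MEASUREMENTS = ("M", "MW")
CORPUS_MEASUREMENTS = ("B", "CSW1", "CSW2")


class MeasurementError(RuntimeError):
    """Raised when required landmarks cannot be located on a contour."""


@dataclass(frozen=True)
class LandmarkParams:
    """Numerical knobs of landmark detection.

    resample_step : arc-length spacing (px) of the resampled contour.
    smooth_window : circular moving-average window (samples) applied to the
        resampled contour; odd.
    boundary_offset : outward normal offset (px) applied before measuring.
        Pixel-traced contours pass through the centers of the outermost
        foreground pixels, about half a pixel inside the physical silhouette
        edge; the measurement pipeline therefore uses 0.5.  For exact
        geometric input (polygons, unit tests) the default is 0.
    notch_prominence : minimum indentation-profile prominence (px) for a
        costal-notch candidate.
    notch_min_sep : minimum arc separation (samples) between notch candidates.
    notch_prominence_window : window length (samples) for the locally
        computed peak prominence.
    confidence_floor : configurations with lower confidence are flagged
        (``low_confidence``) but still returned.
    """

    resample_step: float = 1.0
    smooth_window: int = 5
    boundary_offset: float = 0.0
    notch_prominence: float = 1.0
    notch_min_sep: int = 6
    notch_prominence_window: int = 41
    confidence_floor: float = 0.3


#: parameters used by the automatic pipeline on pixel-traced contours
PIPELINE_LANDMARK_PARAMS = LandmarkParams(boundary_offset=0.5)


@dataclass
class LandmarkConfiguration:
    """Start/end landmark pairs (px) with confidences for one bone."""

    kind: str
    landmarks: dict  # name -> ((x1, y1), (x2, y2))
    confidences: dict  # name -> float in [0, 1]
    low_confidence: bool = False

    def __post_init__(self):
        for name, (a, b) in self.landmarks.items():
            if np.allclose(a, b):
                raise ValueError(f"landmark pair for {name} is degenerate")

    def length_px(self, name: str) -> float:
        (x1, y1), (x2, y2) = self.landmarks[name]
        return float(np.hypot(x2 - x1, y2 - y1))


@dataclass
class MeasurementRecord:
    """The five standard osteometric lengths (cm) for one subject/source."""

    subject_id: str = ""
    source: str = "automatic"  # "manual" | "automatic"
    M: Optional[float] = None
    MW: Optional[float] = None
    B: Optional[float] = None
    CSW1: Optional[float] = None
    CSW2: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self):
        if self.source not in ("manual", "automatic"):
            raise ValueError(f"source must be manual|automatic, got {self.source!r}")
        for name in ("M", "MW", "B", "CSW1", "CSW2"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 (cm), got {v}")

    def values(self) -> dict:
        return {k: getattr(self, k) for k in ("M", "MW", "B", "CSW1", "CSW2")
                if getattr(self, k) is not None}


@dataclass(frozen=True)
class IndexRecord:
    """Sternal index SI = 100*M/B, sternal area SA (cm^2), combined length CL."""

    SI: float
    SA: float
    CL: float


@dataclass
class TrainingResult:
    """Outcome of the segmentation-parameter training loop."""

    params: SegmentationParams
    efficiency: float
    tolerance: float
    grid: list

    def __post_init__(self):
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")


# ---------------------------------------------------------------------------
# contour preprocessing
# ---------------------------------------------------------------------------

def _resample_closed(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a closed polygon at uniform arc length (open representation)."""
    pts = np.asarray(points, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = seg > 1e-12
    pts = np.vstack([pts[:-1][keep], pts[-1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(round(total / step)), 8)
    s = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y])


def _smooth_closed(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    if window % 2 == 0:
        window += 1
    k = np.ones(window) / window
    out = np.empty_like(points)
    for j in (0, 1):
        ext = np.concatenate([points[-(window // 2):, j], points[:, j],
                              points[: window // 2, j]])
        out[:, j] = np.convolve(ext, k, mode="valid")
    return out


def _offset_outward(points: np.ndarray, delta: float) -> np.ndarray:
    """Offset a closed (open-representation) polygon along outward normals."""
    if delta == 0:
        return points
    nxt = np.roll(points, -1, axis=0)
    prv = np.roll(points, 1, axis=0)
    tang = nxt - prv
    norms = np.column_stack([tang[:, 1], -tang[:, 0]])
    lens = np.linalg.norm(norms, axis=1, keepdims=True)
    norms = norms / np.maximum(lens, 1e-12)
    # orient outward: positive signed area (CCW in y-down frame) -> flip check
    x, y = points[:, 0], points[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed > 0:
        norms = -norms
    # verify with the centroid: outward normals point away from it
    c = points.mean(axis=0)
    if np.mean(np.einsum("ij,ij->i", points - c, norms)) < 0:
        norms = -norms
    return points + delta * norms


def _principal_frame(points: np.ndarray):
    """Centroid and unit principal axes of the contour point cloud."""
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, v = np.linalg.eigh(cov)
    major, minor = v[:, np.argmax(w)], v[:, np.argmin(w)]
    return c, major, minor


def _asymmetry(poly: Polygon, center: np.ndarray, axis: np.ndarray) -> float:
    """Area of the symmetric difference after reflection across the axis."""
    a = axis / np.linalg.norm(axis)
    pts = np.asarray(poly.exterior.coords)
    rel = pts - center
    t = rel @ a
    s = rel @ np.array([-a[1], a[0]])
    refl = center + np.outer(t, a) + np.outer(-s, np.array([-a[1], a[0]]))
    try:
        other = Polygon(refl)
        if not other.is_valid:
            other = other.buffer(0)
        return poly.symmetric_difference(other).area
    except Exception:
        return float("inf")


def _axis_chord(poly: Polygon, p1: np.ndarray, p2: np.ndarray):
    """Extreme intersection points of the infinite line p1-p2 with a polygon."""
    d = p2 - p1
    n = np.linalg.norm(d)
    if n < 1e-9:
        return None
    d = d / n
    span = 4.0 * math.sqrt(poly.bounds[2] - poly.bounds[0] + poly.bounds[3] - poly.bounds[1] + 1) ** 2
    line = LineString([p1 - span * d, p1 + span * d])
    inter = line.intersection(poly)
    if inter.is_empty:
        return None
    coords = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        coords.extend(np.asarray(g.coords))
    coords = np.asarray(coords)
    proj = (coords - p1) @ d
    return coords[np.argmin(proj)], coords[np.argmax(proj)]


# ---------------------------------------------------------------------------
# landmark detection
# ---------------------------------------------------------------------------

def _midline_frame(pts: np.ndarray):
    """Anatomical frame: midline axis via reflection symmetry.

    Both bones are bilaterally symmetric, so the midline is the axis of
    minimal reflection asymmetry.  The angle is found by a coarse scan over
    the half-circle followed by a bisection refinement (the two principal
    axes alone are unreliable when the bone is nearly as wide as long and
    the inertia tensor is almost degenerate).  Returns (center, v_hat,
    u_hat, polygon): v_hat along the midline, u_hat lateral.
    """
    c = pts.mean(axis=0)
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    # decimated copy for the angular search
    probe = Polygon(pts[:: max(1, len(pts) // 300)])
    if not probe.is_valid:
        probe = probe.buffer(0)

    def axis(angle):
        return np.array([np.cos(angle), np.sin(angle)])

    def score(angle):
        return _asymmetry(probe, c, axis(angle))

    _, major, _ = _principal_frame(pts)
    major_angle = float(np.arctan2(major[1], major[0])) % np.pi
    angles = np.append(np.arange(0.0, np.pi, np.pi / 12), major_angle)
    scores = np.array([score(a) for a in angles])
    # near-ties (e.g. fully symmetric shapes) resolve to the major axis
    tol = min(scores) + 2e-3 * probe.area + 1e-9
    eligible = angles[scores <= tol]
    gap = np.abs((eligible - major_angle + np.pi / 2) % np.pi - np.pi / 2)
    best = float(eligible[int(np.argmin(gap))])
    step = np.pi / 12
    while step > np.pi / 720:  # refine to ~0.25 degrees
        step /= 2
        trio = {best: score(best), best - step: score(best - step),
                best + step: score(best + step)}
        best = min(trio, key=trio.get)
    v_hat = axis(best)
    u_hat = np.array([-v_hat[1], v_hat[0]])
    return c, v_hat, u_hat, poly


def _midline_crossings(poly: Polygon, c: np.ndarray, v_hat: np.ndarray):
    res = _axis_chord(poly, c, c + v_hat)
    if res is None:
        raise MeasurementError("contour does not intersect its midline")
    return np.asarray(res[0]), np.asarray(res[1])  # min-t, max-t


def _arc_split(t: np.ndarray, s: np.ndarray):
    """Split the closed sequence into the two lateral arcs.

    The contour is cut at its two extreme points along the midline (the
    superior and inferior tips); the two traversal arcs between the cuts are
    the lateral borders.  Returns (idx_right, idx_left) index arrays with
    s > 0 and s < 0 on the right and left arc respectively.
    """
    n = len(s)
    i_top, i_bot = int(np.argmin(t)), int(np.argmax(t))
    if i_top == i_bot:
        raise MeasurementError("degenerate contour: no midline extent")
    if i_top < i_bot:
        arc1 = np.arange(i_top, i_bot + 1)
        arc2 = np.concatenate([np.arange(i_bot, n), np.arange(0, i_top + 1)])
    else:
        arc1 = np.concatenate([np.arange(i_top, n), np.arange(0, i_bot + 1)])
        arc2 = np.arange(i_bot, i_top + 1)
    if np.median(s[arc1]) >= 0:
        return arc1, arc2
    return arc2, arc1


def _indentation_peaks(depth: np.ndarray, params: LandmarkParams):
    """Local maxima of an indentation profile with prominences."""
    peaks, props = find_peaks(depth, prominence=params.notch_prominence,
                              distance=params.notch_min_sep)
    return peaks, props.get("prominences", np.zeros(0))


def _notches_on_arc(pts: np.ndarray, t: np.ndarray, s: np.ndarray,
                    idx: np.ndarray, n_expected: int, params: LandmarkParams):
    """Find costal notches (indentations of |s|) on one lateral arc.

    Notches are local maxima of the indentation profile -|s| with a locally
    windowed prominence (so the rounded end caps, where the width falls to
    zero, do not mask the outermost notches).  Candidates inside the caps
    themselves are rejected by a width-level floor at half the arc's upper
    width quantile.
    """
    sel = np.asarray(idx)
    if len(sel) < 8:
        return [], np.zeros(0)
    width = np.abs(s[sel])
    depth = -width
    peaks, props = find_peaks(depth - depth.min(),
                              prominence=params.notch_prominence,
                              distance=params.notch_min_sep,
                              wlen=params.notch_prominence_window)
    prom = props.get("prominences", np.zeros(0))
    if len(peaks) == 0:
        return [], np.zeros(0)
    level = 0.5 * np.quantile(width, 0.9)
    keep = width[peaks] >= level
    peaks, prom = peaks[keep], prom[keep]
    if len(peaks) == 0:
        return [], np.zeros(0)
    if len(peaks) > n_expected:
        best = np.argsort(prom)[::-1][:n_expected]
        peaks, prom = peaks[np.sort(best)], prom[np.sort(best)]
    chosen = sel[peaks]
    order = np.argsort(t[chosen])
    return list(chosen[order]), prom[order]


def _robust_section_chord(poly: Polygon, m_l: np.ndarray, m_r: np.ndarray,
                          offsets=(-9.0, -6.0, -3.0, 0.0, 3.0, 6.0, 9.0)):
    """Width chord through a section line, robust to local border dents.

    The chord is sampled on parallel lines offset along the section normal;
    each side's lateral extent is fit linearly against the offset with
    one-sided outlier rejection (border-break dents only ever shorten a
    chord) and evaluated at offset zero.  Returns (left point, right point)
    on the central section line, or None.
    """
    d = m_r - m_l
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        return None
    d = d / nd
    n = np.array([-d[1], d[0]])
    o0 = 0.5 * (m_l + m_r)

    offs, los, his = [], [], []
    for off in offsets:
        res = _axis_chord(poly, o0 + off * n, o0 + off * n + d)
        if res is None:
            continue
        proj = [(np.asarray(p) - o0) @ d for p in res]
        offs.append(off)
        los.append(min(proj))
        his.append(max(proj))
    if not offs:
        return None
    offs = np.asarray(offs)

    def detrended(vals, sign):
        # sign +1: dents push values down (right side); -1: up (left side)
        v = np.asarray(vals)
        keep = np.ones(len(v), dtype=bool)
        for _ in range(2):
            if keep.sum() < 2:
                break
            a, b = np.polyfit(offs[keep], v[keep], 1)
            resid = (v - (a * offs + b)) * sign
            new_keep = resid > -1.0
            if new_keep.sum() >= 2:
                keep = new_keep
        if keep.sum() >= 2:
            a, b = np.polyfit(offs[keep], v[keep], 1)
            return float(b)
        return float(v[np.argmin(np.abs(offs))])

    lo0 = detrended(los, -1.0)
    hi0 = detrended(his, +1.0)
    if hi0 <= lo0:
        return None
    # bilateral-symmetry guard: the section origin lies on the midline, so
    # the two half-widths agree on an intact border; a break dent only ever
    # shortens its side, so a clear disagreement means the larger side is
    # the intact one
    if abs(hi0) - abs(lo0) > 2.0:
        lo0 = -hi0
    elif abs(lo0) - abs(hi0) > 2.0:
        hi0 = -lo0
    return o0 + lo0 * d, o0 + hi0 * d


def _pair_notches(t: np.ndarray, nr, pr, nl, pl, n_expected: int,
                  tol: float = 8.0):
    """Match notch candidates across the two lateral borders.

    Costal notches are bilateral: a genuine notch appears at nearly the same
    midline position on both sides, while one-sided artifacts (border-break
    dents) do not.  Greedy nearest-level matching within ``tol`` px; if more
    than ``n_expected`` pairs match, the most prominent pairs are kept.
    Returns a list of (right index, left index, prominence) ordered
    superior -> inferior.
    """
    cand = []
    for i in range(len(nr)):
        for j in range(len(nl)):
            dt = abs(t[nr[i]] - t[nl[j]])
            if dt <= tol:
                cand.append((dt, i, j))
    cand.sort(key=lambda x: x[0])
    used_r: set = set()
    used_l: set = set()
    pairs = []
    for dt, i, j in cand:
        if i in used_r or j in used_l:
            continue
        used_r.add(i)
        used_l.add(j)
        pairs.append((nr[i], nl[j], float(min(pr[i], pl[j]))))
    singles = [(nr[i], float(pr[i]), "right") for i in range(len(nr))
               if i not in used_r]
    singles += [(nl[j], float(pl[j]), "left") for j in range(len(nl))
                if j not in used_l]
    if len(pairs) > n_expected:
        pairs.sort(key=lambda x: -x[2])
        pairs = pairs[:n_expected]
    pairs.sort(key=lambda x: t[x[0]])
    return pairs, singles


def find_landmarks(contour: Contour, kind: str,
                   params: LandmarkParams | None = None,
                   strict: bool = True) -> LandmarkConfiguration:
    """Locate the measurement landmarks on an accepted contour.

    With ``strict`` (default) every measurement defined on the bone must be
    resolvable, otherwise a :class:`MeasurementError` lists what is missing;
    with ``strict=False`` a partial configuration is returned.
    """
    if kind not in ("manubrium", "corpus"):
        raise ValueError(f"kind must be manubrium|corpus, got {kind!r}")
    params = params or LandmarkParams()

    pts = _resample_closed(contour.points, params.resample_step)
    pts = _smooth_closed(pts, params.smooth_window)
    pts = _offset_outward(pts, params.boundary_offset)
    c, v_hat, u_hat, poly = _midline_frame(pts)
    t = (pts - c) @ v_hat
    s = (pts - c) @ u_hat

    landmarks: dict = {}
    confidences: dict = {}
    missing: list[str] = []

    if kind == "corpus":
        _corpus_landmarks(pts, t, s, c, v_hat, u_hat, poly, params,
                          landmarks, confidences, missing)
    else:
        _manubrium_landmarks(pts, t, s, c, v_hat, u_hat, poly, params,
                             landmarks, confidences, missing)

    if missing and strict:
        raise MeasurementError(
            f"required landmarks not found on {kind}: {', '.join(missing)}")
    if not landmarks:
        raise MeasurementError(f"no landmarks found on {kind}")
    low = any(v < params.confidence_floor for v in confidences.values())
    return LandmarkConfiguration(kind=kind, landmarks=landmarks,
                                 confidences=confidences, low_confidence=low)


def _tip_rises(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Per-end tip elongation: distance from each midline extreme until the
    width reaches 70% of the width prevailing near that end.

    The reference width is local (median half-width in the 10-35% span band
    adjacent to the end), so a shaft that widens or narrows along its length
    does not bias the measure.
    """
    w = np.abs(s)
    span = t.max() - t.min()
    if span <= 0:
        return 0.0, 0.0
    rises = []
    for d in (t - t.min(), t.max() - t):
        band = (d >= 0.10 * span) & (d <= 0.35 * span)
        if not band.any():
            rises.append(0.0)
            continue
        level = 0.7 * np.median(w[band])
        m = w >= level
        rises.append(float(d[m].min()) if m.any() else 0.0)
    return rises[0], rises[1]


def _orient_corpus(t, s, params):
    """Flip t so the elongated (xiphoid-ward) taper lies at large t.

    The sternal body ends bluntly at the manubriosternal junction and
    tapers gradually toward the mesoxiphoid junction, so the end with the
    longer rise to full width is inferior.
    """
    r_min_end, r_max_end = _tip_rises(t, s)
    return (-t, True) if r_min_end > r_max_end else (t, False)


def _corpus_landmarks(pts, t, s, c, v_hat, u_hat, poly, params,
                      landmarks, confidences, missing):
    t, flipped = _orient_corpus(t, s, params)
    v = -v_hat if flipped else v_hat

    p_sup, p_inf = _midline_crossings(poly, c, v)
    landmarks["B"] = (tuple(p_sup), tuple(p_inf))
    confidences["B"] = 0.95

    right_idx, left_idx = _arc_split(t, s)
    nr, pr = _notches_on_arc(pts, t, s, right_idx, 7, params)
    nl, pl = _notches_on_arc(pts, t, s, left_idx, 7, params)
    pairs, singles = _pair_notches(t, nr, pr, nl, pl, 7)

    # assign bilateral pairs (preferred) and one-sided candidates (mirrored
    # across the midline) to the five notch slots, evenly spaced along the
    # shaft between the two end caps
    r_sup, r_inf = _tip_rises(t, s)
    lo = t.min() + 1.3 * r_sup
    hi = t.max() - 1.3 * r_inf
    slot_t = lo + np.array([0.1, 0.3, 0.5, 0.7, 0.9]) * (hi - lo)
    tol = 0.09 * (hi - lo)

    def mirror(p):
        rel = p - c
        return c + (rel @ v) * v - (rel @ u_hat) * u_hat

    slots: dict[int, tuple] = {}  # k -> (p_right, p_left, confidence)
    for ri, li, prom in pairs:
        k = int(np.argmin(np.abs(slot_t - t[ri])))
        if abs(t[ri] - slot_t[k]) > tol:
            continue
        if k in slots and slots[k][2] >= prom / 4.0:
            continue
        slots[k] = (pts[ri], pts[li], min(prom / 4.0, 1.0))
    for idx, prom, side in sorted(singles, key=lambda x: -x[1]):
        k = int(np.argmin(np.abs(slot_t - t[idx])))
        if k in slots or abs(t[idx] - slot_t[k]) > tol:
            continue
        p, q = pts[idx], mirror(pts[idx])
        conf = min(prom / 4.0, 1.0) * 0.5
        slots[k] = (p, q, conf) if side == "right" else (q, p, conf)

    for pair_name, (i, j) in (("CSW1", (1, 2)), ("CSW2", (3, 4))):
        if i not in slots or j not in slots:
            missing.append(f"{pair_name} costal notches (slots "
                           f"{sorted(k + 1 for k in slots)} of 1-5 filled; "
                           f"{len(nr)} right, {len(nl)} left candidates)")
            continue
        m_r = 0.5 * (slots[i][0] + slots[j][0])
        m_l = 0.5 * (slots[i][1] + slots[j][1])
        chord = _robust_section_chord(poly, m_l, m_r)
        if chord is None:
            missing.append(f"{pair_name} section line misses the contour")
            continue
        landmarks[pair_name] = (tuple(chord[0]), tuple(chord[1]))
        confidences[pair_name] = float(min(slots[i][2], slots[j][2]))


def _manubrium_landmarks(pts, t, s, c, v_hat, u_hat, poly, params,
                         landmarks, confidences, missing):
    # orientation: the superior midline crossing is indented (jugular notch)
    # relative to its flanking border, the inferior one is not
    pa, pb = _midline_crossings(poly, c, v_hat)
    S = np.abs(s).max()

    def indentation(p_cross, side_sign):
        ta = (p_cross - c) @ v_hat
        band = (np.abs(s) > 0.25 * S) & (np.abs(s) < 0.65 * S) \
            & (np.sign(t) == side_sign)
        if not band.any():
            return 0.0
        flank_ext = t[band].min() if side_sign < 0 else -t[band].max()
        cross_ext = ta if side_sign < 0 else -ta
        return float(cross_ext - flank_ext)  # > 0 when crossing is indented

    ind_a = indentation(np.asarray(pa), -1.0)
    ind_b = indentation(np.asarray(pb), +1.0)
    if ind_b > ind_a:
        v_hat, u_hat = -v_hat, -u_hat
        t, s = -t, -s
        pa, pb = pb, pa
    p_sup_cross, p_inf = np.asarray(pa), np.asarray(pb)
    t_sup = (p_sup_cross - c) @ v_hat

    # superior border band: jugular + clavicular notches
    band = (t < t_sup + 4.0) & (np.abs(s) < 0.90 * S)
    if band.sum() >= 8:
        bs, bt = s[band], t[band]
        bp = pts[band]
        order = np.argsort(bs)
        bs, bt, bp = bs[order], bt[order], bp[order]
        peaks, prom = _indentation_peaks(bt - bt.min(), params)
    else:
        peaks, prom = np.zeros(0, dtype=int), np.zeros(0)

    jug = clav_l = clav_r = None
    if len(peaks):
        near_mid = peaks[np.abs(bs[peaks]) < 0.30 * S]
        if len(near_mid):
            jug = near_mid[np.argmin(np.abs(bs[near_mid]))]
        if jug is not None:
            lefts = peaks[bs[peaks] < bs[jug] - 4.0]
            rights = peaks[bs[peaks] > bs[jug] + 4.0]
            if len(lefts):
                clav_l = lefts[np.argmax(prom[np.isin(peaks, lefts)])]
            if len(rights):
                clav_r = rights[np.argmax(prom[np.isin(peaks, rights)])]
    if jug is None or clav_l is None or clav_r is None:
        want = []
        if jug is None:
            want.append("incisura jugularis")
        if clav_l is None or clav_r is None:
            want.append("incisura clavicularis")
        missing.append("M superior landmarks (" + ", ".join(want) + ")")
    else:
        clav_mid = 0.5 * (bp[clav_l] + bp[clav_r])
        # the jugular floor is the superior midline crossing itself (the
        # notch is bilaterally symmetric about the midline; the band peak
        # only confirms its presence and prominence)
        p_sup = 0.5 * (p_sup_cross + clav_mid)
        landmarks["M"] = (tuple(p_sup), tuple(p_inf))
        prom_jug = prom[np.isin(peaks, [jug])]
        confidences["M"] = float(np.clip(prom_jug[0] / 6.0, 0.0, 1.0)) \
            if len(prom_jug) else 0.5

    # costal notch 1 on each lateral border (bilateral pairing rejects
    # one-sided artifacts)
    right_idx, left_idx = _arc_split(t, s)
    nr, pr = _notches_on_arc(pts, t, s, right_idx, 3, params)
    nl, pl = _notches_on_arc(pts, t, s, left_idx, 3, params)
    pairs, singles = _pair_notches(t, nr, pr, nl, pl, 1)

    def mirror(p):
        rel = p - c
        return c + (rel @ v_hat) * v_hat - (rel @ u_hat) * u_hat

    p_r = p_l = None
    conf = 0.0
    if pairs:
        r_i, l_i, prom = max(pairs, key=lambda x: x[2])
        p_r, p_l = pts[r_i], pts[l_i]
        conf = min(prom / 4.0, 1.0)
    else:
        # one-sided fallback: mirror the best candidate in the plausible
        # band between the clavicular level and the inferior cap
        t_inf = (p_inf - c) @ v_hat
        band_lo = t_sup + 0.25 * (t_inf - t_sup)
        band_hi = t_inf - 0.12 * (t_inf - t_sup)
        usable = [(idx, prom) for idx, prom, _side in singles
                  if band_lo <= t[idx] <= band_hi]
        if usable:
            idx, prom = max(usable, key=lambda x: x[1])
            p_r, p_l = pts[idx], mirror(pts[idx])
            conf = min(prom / 4.0, 1.0) * 0.5
    if p_r is None:
        missing.append("MW costal notch 1 "
                       f"(no bilateral pair or usable candidate; "
                       f"{len(nr)} right, {len(nl)} left candidates)")
    else:
        chord = _axis_chord(poly, p_l, p_r)
        if chord is None:
            missing.append("MW section line misses the contour")
        else:
            landmarks["MW"] = (tuple(chord[0]), tuple(chord[1]))
            confidences["MW"] = float(conf)


# ---------------------------------------------------------------------------
# candidate reduction, measurement, indices
# ---------------------------------------------------------------------------

def cluster_candidates(candidates: Sequence[tuple[float, float]],
                       gap_fraction: float = 0.05):
    """Reduce a stack of (length, confidence) candidates.

    1-D single-linkage clustering: sorted candidates are split wherever the
    gap between neighbours exceeds ``gap_fraction`` x median length.  The
    highest-confidence candidate wins within each cluster, and the winner of
    the most populous cluster (ties -> higher confidence) is the final
    choice.  Returns (winners per cluster, final (length, confidence)).
    """
    cands = [(float(v), float(c)) for v, c in candidates]
    if not cands:
        raise ValueError("cluster_candidates requires at least one candidate")
    cands.sort(key=lambda vc: v_key(vc))
    values = [v for v, _ in cands]
    thr = gap_fraction * float(np.median(values))
    clusters: list[list[tuple[float, float]]] = [[cands[0]]]
    for prev, cur in zip(cands, cands[1:]):
        if cur[0] - prev[0] > thr:
            clusters.append([cur])
        else:
            clusters[-1].append(cur)
    winners = [max(cl, key=lambda vc: vc[1]) for cl in clusters]
    sizes = [len(cl) for cl in clusters]
    best = max(range(len(clusters)),
               key=lambda i: (sizes[i], winners[i][1]))
    return winners, winners[best]


def v_key(vc):
    return vc[0]


def measure_bone(contour: Contour, landmarks: LandmarkConfiguration,
                 spacing: float, subject_id: str = "") -> MeasurementRecord:
    """Convert a landmark configuration to centimeters (source=automatic)."""
    if not spacing > 0:
        raise ValueError(f"spacing must be > 0 cm/px, got {spacing}")
    vals = {name: landmarks.length_px(name) * spacing
            for name in landmarks.landmarks}
    return MeasurementRecord(subject_id=subject_id, source="automatic", **vals)


def compute_indices(record: MeasurementRecord) -> IndexRecord:
    """SI = 100*M/B, SA = (M+B)(MW+CSW1+CSW2)/3, CL = M+B."""
    missing = [n for n in ("M", "MW", "B", "CSW1", "CSW2")
               if getattr(record, n) is None]
    if missing:
        raise ValueError(f"missing measurements: {', '.join(missing)}")
    M, MW, B = record.M, record.MW, record.B
    CSW1, CSW2 = record.CSW1, record.CSW2
    return IndexRecord(SI=100.0 * M / B,
                       SA=(M + B) * (MW + CSW1 + CSW2) / 3.0,
                       CL=M + B)


# ---------------------------------------------------------------------------
# full measurement of one image + training loop
# ---------------------------------------------------------------------------

def measure_image(image: BoneImage,
                  seg_params: SegmentationParams | None = None,
                  landmark_params: LandmarkParams = PIPELINE_LANDMARK_PARAMS,
                  smooth_windows: Sequence[int] = (5, 7, 9),
                  subject_id: str = "") -> MeasurementRecord:
    """Segment one image and measure it.

    The landmark stage is run at several contour smoothing windows; the
    resulting stack of length candidates per measurement is reduced with
    :func:`cluster_candidates` ("finding the best candidate in each
    cluster").
    """
    contour = segment_bone(image, seg_params)
    kind = image.kind if image.kind in ("manubrium", "corpus") else None
    if kind is None:
        raise MeasurementError("bone kind unknown; cannot select landmarks")
    stacks: dict[str, list[tuple[float, float]]] = {}
    err: Exception | None = None
    for w in smooth_windows:
        try:
            cfg = find_landmarks(contour, kind,
                                 replace(landmark_params, smooth_window=w))
        except MeasurementError as e:
            err = e
            continue
        for name in cfg.landmarks:
            stacks.setdefault(name, []).append(
                (cfg.length_px(name) * image.spacing, cfg.confidences[name]))
    expected = MANUBRIUM_MEASUREMENTS if kind == "manubrium" else CORPUS_MEASUREMENTS
    if not stacks or any(m not in stacks for m in expected):
        raise err if err is not None else MeasurementError(
            f"no landmark candidates on {kind}")
    vals = {}
    for name, cands in stacks.items():
        _, (best, _conf) = cluster_candidates(cands)
        vals[name] = best
    return MeasurementRecord(subject_id=subject_id or image.ident,
                             source="automatic", **vals)


def default_parameter_grid() -> list[SegmentationParams]:
    """The default segmentation-parameter grid searched during training."""
    grid = []
    for offset in (60.0, 80.0, 100.0):
        for pot_thr in (2.0, 2.5):
            for window in (121, 151):
                grid.append(SegmentationParams(
                    window=window, offset=offset, potential_threshold=pot_thr))
    return grid


def _reference_lengths(ref) -> dict:
    from .phantom import PhantomTruth
    if isinstance(ref, PhantomTruth):
        return dict(ref.lengths)
    if isinstance(ref, MeasurementRecord):
        return ref.values()
    if isinstance(ref, Mapping):
        return dict(ref)
    raise TypeError(f"unsupported reference type {type(ref)!r}")


def tune_parameters(training: Sequence[tuple], grid: Sequence[SegmentationParams] | None = None,
                    tolerance: float = 0.05,
                    landmark_params: LandmarkParams = PIPELINE_LANDMARK_PARAMS) -> TrainingResult:
    """Exhaustive grid search of the segmentation parameters.

    ``training`` is a sequence of (BoneImage, reference) pairs where the
    reference is a PhantomTruth, a MeasurementRecord or a plain mapping of
    lengths (cm).  Efficiency of a parameter set = fraction of training
    images that segment successfully with every defined measurement within
    ``tolerance`` relative error of its reference.  The first argmax of the
    grid wins (deterministic).
    """
    if not training:
        raise ValueError("training set must not be empty")
    grid = list(grid) if grid is not None else default_parameter_grid()
    if not grid:
        raise ValueError("parameter grid must not be empty")
    best_params, best_eff = None, -1.0
    for params in grid:
        ok = 0
        for image, ref in training:
            refs = _reference_lengths(ref)
            try:
                rec = measure_image(image, params, landmark_params)
            except (SegmentationError, MeasurementError, ValueError):
                continue
            got = rec.values()
            if all(name in got
                   and abs(got[name] - v) <= tolerance * v
                   for name, v in refs.items()):
                ok += 1
        eff = ok / len(training)
        if eff > best_eff:
            best_params, best_eff = params, eff
    return TrainingResult(params=best_params, efficiency=best_eff,
                          tolerance=tolerance, grid=grid)
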