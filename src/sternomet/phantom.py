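"""Synthetic sternal phantoms with exactly known osteometric ground truth.

Generates en-face projection images of the two sternal segments:

* **manubrium** -- a broad, superiorly widest plate carrying the jugular
  notch (midline superior concavity), two clavicular notches, and the first
  costal notch on each lateral border.  Defined measurements: manubrium
  length M and manubrium width MW.
* **corpus** (sternal body) -- an elongated blade with five costal-notch
  indentations per lateral border.  Defined measurements: body length B and
  the body widths CSW1 (level of the costal notch 2/3 midpoints) and CSW2
  (level of the costal notch 4/5 midpoints).

Outlines are smooth parametric curves (shape-preserving cubic width profiles
with flat-floored notch bumps), so every landmark is known at sub-pixel
precision.  A population sampler draws per-subject measurement sets from a
sex-structured multivariate normal whose pooled moments match the reference
measurement table, and a corruption model adds the failure modes automatic
segmentation must survive: intensity noise, illumination gradients, border
breaks and distractor structures.

Coordinates are (x, y) pixel pairs, origin at the top-left pixel center,
y increasing downward.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import distance_transform_edt
from scipy.stats import norm
from skimage.draw import polygon as draw_polygon

from .segmentation import BoneImage

__all__ = [
    "PopulationSpec",
    "PhantomTruth",
    "CorruptionSpec",
    "MEASUREMENTS",
    "CORPUS_MEASUREMENTS",
    "MANUBRIUM_MEASUREMENTS",
    "DEFAULT_SPACING",
    "sample_ground_truth",
    "render_phantom",
    "corrupt_image",
]

MEASUREMENTS = ("M", "MW", "B", "CSW1", "CSW2")
MANUBRIUM_MEASUREMENTS = ("M", "MW")
CORPUS_MEASUREMENTS = ("B", "CSW1", "CSW2")

#: default physical pixel size, cm/pixel
DEFAULT_SPACING = 0.05

# Pooled reference moments (cm) of the five standard measurements in the
# target population (manual reference values).
POOLED_MEAN = {"M": 5.23, "MW": 5.63, "B": 9.46, "CSW1": 2.65, "CSW2": 3.12}
POOLED_SD = {"M": 0.53, "MW": 0.53, "B": 1.44, "CSW1": 0.36, "CSW2": 0.56}

# Sexual-dimorphism separation d (Mahalanobis distance between sex means in
# within-sex SD units) per measurement, chosen so that a midpoint-threshold
# classifier on each single variable reproduces its published classification
# rate: d = 2 * Phi^-1(rate).
DIMORPHISM_D = {
    "M": 2 * norm.ppf(0.680),
    "MW": 2 * norm.ppf(0.789),
    "B": 2 * norm.ppf(0.828),
    "CSW1": 2 * norm.ppf(0.734),
    "CSW2": 2 * norm.ppf(0.672),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Sex-structured population model for the five sternal measurements.

    Pooled means/SDs are split into per-sex means and a common within-sex SD
    so that mixing the sexes at the given sample sizes reproduces the pooled
    moments:  with male fraction p and separation ``d`` (within-sex SD
    units), sd_within = sd_pooled / sqrt(1 + p(1-p) d^2), the male mean is
    shifted up by (1-p)*d*sd_within and the female mean down by p*d*sd_within.

    ``correlation`` is the single inter-measurement correlation of the
    within-sex equicorrelated covariance.
    """

    means: dict = field(default_factory=lambda: dict(POOLED_MEAN))
    sds: dict = field(default_factory=lambda: dict(POOLED_SD))
    dimorphism: dict = field(default_factory=lambda: dict(DIMORPHISM_D))
    correlation: float = 0.5
    n_male: int = 73
    n_female: int = 55
    seed: int = 0

    def __post_init__(self):
        for m in MEASUREMENTS:
            if not self.means.get(m, 0) > 0:
                raise ValueError(f"mean of {m} must be > 0")
            if self.sds.get(m, -1) < 0:
                raise ValueError(f"SD of {m} must be >= 0")
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must be in [0, 1)")
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("sample sizes must be >= 0")

    def sex_parameters(self) -> dict:
        """Per-sex means and the common within-sex SDs, all in cm."""
        n = self.n_male + self.n_female
        p = self.n_male / n if n else 0.5
        out = {"male": {}, "female": {}, "sd_within": {}}
        for m in MEASUREMENTS:
            d = self.dimorphism[m]
            sw = self.sds[m] / np.sqrt(1.0 + p * (1 - p) * d * d)
            delta = d * sw
            out["male"][m] = self.means[m] + (1 - p) * delta
            out["female"][m] = self.means[m] - p * delta
            out["sd_within"][m] = sw
        return out


@dataclass
class PhantomTruth:
    """Ground truth of one rendered phantom.

    lengths : measurement name -> true length (cm).
    landmarks : measurement name -> ((x1, y1), (x2, y2)) pixel endpoints.
    outline : (N, 2) closed polygon of the true silhouette, pixel units.
    """

    kind: str
    lengths: dict
    landmarks: dict
    spacing: float
    seed: int
    outline: np.ndarray | None = None

    def __post_init__(self):
        expected = set(MANUBRIUM_MEASUREMENTS if self.kind == "manubrium"
                       else CORPUS_MEASUREMENTS)
        if set(self.lengths) != expected:
            raise ValueError(
                f"{self.kind} truth must carry exactly {sorted(expected)}")
        for m, ((x1, y1), (x2, y2)) in self.landmarks.items():
            d = np.hypot(x2 - x1, y2 - y1) * self.spacing
            if abs(d - self.lengths[m]) > 1e-6:
                raise ValueError(
                    f"landmark distance for {m} ({d:.8f} cm) does not match "
                    f"stated length {self.lengths[m]:.8f} cm")

    def landmark_length(self, measure: str) -> float:
        (x1, y1), (x2, y2) = self.landmarks[measure]
        return float(np.hypot(x2 - x1, y2 - y1) * self.spacing)

    def to_json(self) -> str:
        d = {
            "kind": self.kind,
            "lengths": self.lengths,
            "landmarks": {k: [list(a), list(b)] for k, (a, b) in self.landmarks.items()},
            "spacing": self.spacing,
            "seed": self.seed,
            "outline": None if self.outline is None else np.asarray(self.outline).tolist(),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            lengths={k: float(v) for k, v in d["lengths"].items()},
            landmarks={k: (tuple(v[0]), tuple(v[1])) for k, v in d["landmarks"].items()},
            spacing=float(d["spacing"]),
            seed=int(d["seed"]),
            outline=None if d.get("outline") is None else np.asarray(d["outline"]),
        )


@dataclass(frozen=True)
class CorruptionSpec:
    """Image corruption model (all artifact types optional).

    noise_sd : additive Gaussian intensity noise SD.
    n_breaks / break_arc_px / break_radius_px : number of border arcs erased
        to background intensity, their arc length, and the erasure radius.
    n_distractors / distractor_radius / distractor_intensity : bright blob
        structures added away from the bone.
    gradient_amplitude : peak-to-peak linear illumination gradient.
    background_intensity : value breaks are erased to.
    """

    noise_sd: float = 25.0
    n_breaks: int = 2
    break_arc_px: float = 10.0
    break_radius_px: float = 2.0
    n_distractors: int = 3
    distractor_radius: tuple[float, float] = (4.0, 9.0)
    distractor_intensity: float = 700.0
    gradient_amplitude: float = 60.0
    background_intensity: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.n_breaks < 0 or self.n_distractors < 0:
            raise ValueError("corruption counts and noise SD must be >= 0")
        if self.break_arc_px < 0 or self.break_radius_px < 0:
            raise ValueError("break geometry must be >= 0")
        if self.gradient_amplitude < 0:
            raise ValueError("gradient_amplitude must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.noise_sd == 0 and self.n_breaks == 0
                and self.n_distractors == 0 and self.gradient_amplitude == 0)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

def sample_ground_truth(spec: PopulationSpec) -> pd.DataFrame:
    """Draw per-subject true measurement sets from the population model.

    Returns a DataFrame with columns subject_id, sex, M, MW, B, CSW1, CSW2
    (cm).  Reproducible for a given spec (seeded).  Negative draws (possible
    only for extreme specs) are rejected and redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(MEASUREMENTS)
    rho = spec.correlation
    corr = np.full((k, k), rho) + np.eye(k) * (1 - rho)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:  # pragma: no cover - rho in [0,1) is PD
        raise ValueError(
            f"implied correlation matrix (rho={rho}) is not positive "
            f"definite") from e
    pars = spec.sex_parameters()
    sw = np.array([pars["sd_within"][m] for m in MEASUREMENTS])

    rows = []
    for sex, n in (("male", spec.n_male), ("female", spec.n_female)):
        mu = np.array([pars[sex][m] for m in MEASUREMENTS])
        for i in range(n):
            for _ in range(100):
                z = rng.standard_normal(k)
                vals = mu + sw * (chol @ z)
                if np.all(vals > 0):
                    break
            else:
                raise ValueError(
                    "could not draw positive measurements; check means/SDs")
            rows.append({"subject_id": f"{sex[0]}{i:03d}", "sex": sex,
                         **dict(zip(MEASUREMENTS, vals))})
    return pd.DataFrame(rows, columns=["subject_id", "sex", *MEASUREMENTS])


# ---------------------------------------------------------------------------
# outline geometry (local frame, cm; x = lateral from midline, y = inferior)
# ---------------------------------------------------------------------------

NOTCH_DEPTH = 0.20       # cm, corpus costal notch depth
NOTCH_HALFWIDTH = 0.28   # cm, corpus costal notch half-width (flat-floored bump)
MAN_NOTCH_DEPTH = 0.30   # cm, manubrium costal notch 1 (deeper: marked notch)
MAN_NOTCH_HALFWIDTH = 0.35
CAP_SUP = 0.35           # cm, blunt superior end cap (manubriosternal junction)
CAP_INF = 0.80           # cm, elongated inferior taper (toward the xiphoid)
MAN_CAP = 0.30           # cm, manubrium inferior cap depth
JUG_DEPTH = 0.55         # cm, jugular notch depth
JUG_HALFWIDTH = 0.65     # cm
CLAV_DEPTH = 0.30        # cm, clavicular notch depth
CLAV_HALFWIDTH = 0.35    # cm
#: costal notch positions as fractions of the shaft (body length minus caps)
CORPUS_NOTCH_FRACTIONS = (0.08, 0.28, 0.48, 0.68, 0.88)


def _bump(t: np.ndarray | float) -> np.ndarray | float:
    """Smooth flat-topped unit bump with compact effective support (|t|<~1.5)."""
    return np.exp(-np.asarray(t, dtype=float) ** 6)


def _gauss_bump(t: np.ndarray | float) -> np.ndarray | float:
    """Gaussian unit bump; its unique minimum keeps a notch floor localized."""
    return np.exp(-np.asarray(t, dtype=float) ** 2)


def _corpus_geometry(B: float, CSW1: float, CSW2: float, ds: float = 0.02):
    """Closed outline polygon (cm) + true landmarks of a sternal body.

    The superior end (manubriosternal junction) is a blunt cap; the
    inferior end tapers into an elongated point toward the mesoxiphoid
    junction — the polarity cue the landmark stage relies on.  The five
    costal notches sit at fixed fractions of the shaft between the caps.
    """
    if min(B, CSW1, CSW2) <= 0:
        raise ValueError("lengths must be positive")
    if B < 2.2 * (CAP_SUP + CAP_INF):
        raise ValueError(f"body length B={B} too short for the shape model")
    shaft = B - CAP_SUP - CAP_INF
    notch_y = CAP_SUP + np.array(CORPUS_NOTCH_FRACTIONS) * shaft
    y23 = 0.5 * (notch_y[1] + notch_y[2])
    y45 = 0.5 * (notch_y[3] + notch_y[4])
    half = PchipInterpolator(
        [0.0, y23, y45, B],
        [0.47 * CSW1, 0.5 * CSW1, 0.5 * CSW2, 0.30 * CSW2])

    def border_x(y):
        y = np.asarray(y, dtype=float)
        dent = sum(NOTCH_DEPTH * _bump((y - yn) / NOTCH_HALFWIDTH) for yn in notch_y)
        return half(y) - dent

    if np.any(border_x(notch_y) <= 0.05):
        raise ValueError("widths too small for the notch depth")

    # right side, top tip -> bottom tip; blunt cubic cap above, elongated
    # power-1.5 taper below
    h_s, h_i = float(half(CAP_SUP)), float(half(B - CAP_INF))
    xs_top = np.linspace(0, h_s, max(8, int(h_s / ds)))
    top = np.column_stack([xs_top, CAP_SUP * (xs_top / h_s) ** 3])
    ys_lat = np.linspace(CAP_SUP, B - CAP_INF, max(16, int((B - CAP_SUP - CAP_INF) / ds)))
    lat = np.column_stack([border_x(ys_lat), ys_lat])
    xs_bot = np.linspace(h_i, 0, max(12, int(h_i / ds)))
    bot = np.column_stack([xs_bot, B - CAP_INF * (xs_bot / h_i) ** 1.5])
    right = np.vstack([top, lat[1:], bot[1:]])
    left = right[::-1][1:-1] * np.array([-1.0, 1.0])
    poly = np.vstack([right, left, right[:1]])

    landmarks = {
        "B": ((0.0, 0.0), (0.0, B)),
        "CSW1": ((-float(border_x(y23)), y23), (float(border_x(y23)), y23)),
        "CSW2": ((-float(border_x(y45)), y45), (float(border_x(y45)), y45)),
    }
    return poly, landmarks


def _manubrium_geometry(M: float, MW: float, ds: float = 0.02):
    """Closed outline polygon (cm) + true landmarks of a manubrium."""
    if min(M, MW) <= 0:
        raise ValueError("lengths must be positive")
    if M < 2.5 * (JUG_DEPTH + MAN_CAP):
        raise ValueError(f"manubrium length M={M} too short for the shape model")
    H_top = 0.54 * (MW + 2 * MAN_NOTCH_DEPTH)
    x_c = 0.62 * H_top

    def y_sup(x):
        x = np.asarray(x, dtype=float)
        return (JUG_DEPTH * _bump(x / JUG_HALFWIDTH)
                + CLAV_DEPTH * (_bump((x - x_c) / CLAV_HALFWIDTH)
                                + _bump((x + x_c) / CLAV_HALFWIDTH)))

    y_jug = float(y_sup(0.0))
    y_clav = float(y_sup(x_c))
    y_sup_mid = 0.5 * (y_jug + y_clav)
    Y_bot = y_sup_mid + M
    y1 = 0.68 * Y_bot
    # keep the lateral border nearly level through the costal-notch zone
    # (so the notch is a clear local extremum) and taper steeply below it
    h1 = MW / 2 + MAN_NOTCH_DEPTH
    half = PchipInterpolator(
        [0.0, y1 - 0.6, y1, y1 + 0.6, Y_bot],
        [H_top, h1 + 0.04, h1, h1 - 0.04, 0.30 * MW])

    def border_x(y):
        y = np.asarray(y, dtype=float)
        return half(y) - MAN_NOTCH_DEPTH * _gauss_bump(
            (y - y1) / MAN_NOTCH_HALFWIDTH)

    # right half of superior border (midline -> corner), then right lateral,
    # then right half of inferior cap
    xs_sup = np.linspace(0, H_top, max(16, int(H_top / ds)))
    sup = np.column_stack([xs_sup, y_sup(xs_sup)])
    y_corner = Y_bot - MAN_CAP
    ys_lat = np.linspace(y_sup(H_top), y_corner, max(16, int(y_corner / ds)))
    lat = np.column_stack([border_x(ys_lat), ys_lat])
    h_c = float(border_x(y_corner))
    xs_bot = np.linspace(h_c, 0, max(8, int(h_c / ds)))
    bot = np.column_stack([xs_bot, Y_bot - MAN_CAP * (xs_bot / h_c) ** 2])
    right = np.vstack([sup, lat[1:], bot[1:]])
    left = right[::-1][1:-1] * np.array([-1.0, 1.0])
    # traverse: midline of superior border rightwards, down, around, back up
    poly = np.vstack([right, left, right[:1]])

    mw_x = float(border_x(y1))
    landmarks = {
        "M": ((0.0, y_sup_mid), (0.0, Y_bot)),
        "MW": ((-mw_x, y1), (mw_x, y1)),
    }
    return poly, landmarks


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _coverage(poly_px: np.ndarray, shape: tuple[int, int], ss: int = 3) -> np.ndarray:
    """Area-coverage rasterization by ss x ss supersampling."""
    H, W = shape
    hi = np.zeros((H * ss, W * ss), dtype=bool)
    xs = poly_px[:, 0] * ss + (ss - 1) / 2.0
    ys = poly_px[:, 1] * ss + (ss - 1) / 2.0
    rr, cc = draw_polygon(ys, xs, shape=hi.shape)
    hi[rr, cc] = True
    return hi.reshape(H, ss, W, ss).mean(axis=(1, 3))


def render_phantom(truth_lengths: dict, spacing: float = DEFAULT_SPACING,
                   kind: str = "corpus", seed: int = 0, *,
                   margin_px: int = 60, shape: tuple[int, int] | None = None,
                   background: float = 100.0, foreground: float = 1000.0,
                   rim_gain: float = 250.0, rim_width_px: float = 1.5,
                   speckle_sd: float = 25.0) -> tuple[BoneImage, PhantomTruth]:
    """Render one bone phantom and its exact ground truth.

    ``truth_lengths`` carries {B, CSW1, CSW2} for a corpus or {M, MW} for a
    manubrium, in cm.  The bone is drawn as a bright polygon (foreground
    mean intensity with interior speckle and a brighter cortical rim) on a
    dark background, mimicking a CT projection.  The returned PhantomTruth
    stores sub-pixel landmark pairs whose separations reproduce the
    requested lengths exactly, plus the true outline polygon in pixel units.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if kind == "corpus":
        needed = set(CORPUS_MEASUREMENTS)
        if set(truth_lengths) < needed:
            raise ValueError(f"corpus phantom needs lengths {sorted(needed)}")
        poly_cm, lm_cm = _corpus_geometry(
            truth_lengths["B"], truth_lengths["CSW1"], truth_lengths["CSW2"])
    elif kind == "manubrium":
        needed = set(MANUBRIUM_MEASUREMENTS)
        if set(truth_lengths) < needed:
            raise ValueError(f"manubrium phantom needs lengths {sorted(needed)}")
        poly_cm, lm_cm = _manubrium_geometry(
            truth_lengths["M"], truth_lengths["MW"])
    else:
        raise ValueError(f"unknown bone kind {kind!r}")

    xmin, ymin = poly_cm.min(axis=0)
    xmax, ymax = poly_cm.max(axis=0)
    W = int(np.ceil((xmax - xmin) / spacing)) + 2 * margin_px
    H = int(np.ceil((ymax - ymin) / spacing)) + 2 * margin_px
    if shape is not None:
        if H > shape[0] or W > shape[1]:
            raise ValueError(
                f"bone of {ymax - ymin:.2f} x {xmax - xmin:.2f} cm does not "
                f"fit a {shape} canvas at spacing {spacing} cm/px")
        H, W = shape
    if H < 64 or W < 64:
        H, W = max(H, 64), max(W, 64)

    def to_px(p):
        return ((p[..., 0] - xmin) / spacing + margin_px,
                (p[..., 1] - ymin) / spacing + margin_px)

    px, py = to_px(poly_cm)
    poly_px = np.column_stack([px, py])

    cov = _coverage(poly_px, (H, W))
    img = background + cov * (foreground - background)
    mask = cov > 0.5
    edt = distance_transform_edt(mask)
    img[(edt > 0) & (edt <= rim_width_px)] += rim_gain
    rng = np.random.default_rng(seed)
    img += rng.normal(0.0, speckle_sd, size=img.shape) * mask
    img = np.clip(img, 0.0, 65535.0)

    landmarks = {}
    lengths = {}
    for name, (a, b) in lm_cm.items():
        ax, ay = to_px(np.asarray([a]))
        bx, by = to_px(np.asarray([b]))
        p1 = (float(ax[0]), float(ay[0]))
        p2 = (float(bx[0]), float(by[0]))
        landmarks[name] = (p1, p2)
        lengths[name] = float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]) * spacing)

    truth = PhantomTruth(kind=kind, lengths=lengths, landmarks=landmarks,
                         spacing=spacing, seed=seed, outline=poly_px)
    image = BoneImage(pixels=img, spacing=spacing, kind=kind,
                      ident=f"phantom-{kind}-{seed}")
    return image, truth


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def _polyline_distance(points_xy: np.ndarray, seg: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline given as (K, 2) vertices."""
    p = points_xy[:, None, :]                    # (N, 1, 2)
    a = seg[None, :-1, :]                        # (1, K-1, 2)
    b = seg[None, 1:, :]
    ab = b - a
    denom = np.maximum((ab ** 2).sum(-1), 1e-12)
    t = np.clip(((p - a) * ab).sum(-1) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.sqrt(((p - proj) ** 2).sum(-1)).min(axis=1)


def _arc_polyline(outline: np.ndarray, start: float, length: float) -> np.ndarray:
    """Sub-polyline of a closed outline from arc position ``start`` (px)."""
    seglen = np.linalg.norm(np.diff(outline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    ts = np.arange(0.0, length + 0.5, 0.5)
    s = (start + ts) % total
    x = np.interp(s, cum, outline[:, 0])
    y = np.interp(s, cum, outline[:, 1])
    return np.column_stack([x, y])


def corrupt_image(image: BoneImage, truth: PhantomTruth,
                  spec: CorruptionSpec) -> BoneImage:
    """Apply the corruption model; the truth is never modified.

    Order: illumination gradient, additive noise, distractor blobs, border
    breaks (erased last so erased arcs are exactly background intensity).
    With an all-zero spec the input image is returned unchanged (copy).
    """
    if truth.outline is not None and spec.n_breaks > 0:
        perim = np.sum(np.linalg.norm(np.diff(truth.outline, axis=0), axis=1))
        if spec.break_arc_px >= perim / 2:
            raise ValueError("break arc length must be < half the perimeter")
    img = image.pixels.copy()
    if spec.is_identity:
        return BoneImage(img, image.spacing, image.kind, image.ident)
    rng = np.random.default_rng(spec.seed)
    H, W = img.shape
    yy, xx = np.mgrid[0:H, 0:W]

    if spec.gradient_amplitude > 0:
        theta = rng.uniform(0, 2 * np.pi)
        proj = np.cos(theta) * xx + np.sin(theta) * yy
        span = proj.max() - proj.min()
        img += spec.gradient_amplitude * ((proj - proj.min()) / span - 0.5)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    if spec.n_distractors > 0:
        from shapely.geometry import Point, Polygon
        bone = Polygon(truth.outline) if truth.outline is not None else None
        r_lo, r_hi = spec.distractor_radius
        for _ in range(spec.n_distractors):
            r = rng.uniform(r_lo, r_hi)
            for _try in range(200):
                cx = rng.uniform(r + 2, W - r - 2)
                cy = rng.uniform(r + 2, H - r - 2)
                if bone is None or bone.exterior.distance(Point(cx, cy)) > r + 8 \
                        and not bone.contains(Point(cx, cy)):
                    break
            d = np.hypot(xx - cx, yy - cy)
            covg = np.clip(r + 0.5 - d, 0.0, 1.0)
            img += spec.distractor_intensity * covg

    if spec.n_breaks > 0 and truth.outline is not None:
        seglen = np.linalg.norm(np.diff(truth.outline, axis=0), axis=1)
        total = float(np.sum(seglen))
        for _ in range(spec.n_breaks):
            start = rng.uniform(0, total)
            arc = _arc_polyline(truth.outline, start, spec.break_arc_px)
            pad = int(np.ceil(spec.break_radius_px)) + 2
            x0 = max(int(arc[:, 0].min()) - pad, 0)
            x1 = min(int(arc[:, 0].max()) + pad + 1, W)
            y0 = max(int(arc[:, 1].min()) - pad, 0)
            y1 = min(int(arc[:, 1].max()) + pad + 1, H)
            sub = np.column_stack([xx[y0:y1, x0:x1].ravel(),
                                   yy[y0:y1, x0:x1].ravel()]).astype(float)
            dist = _polyline_distance(sub, arc).reshape(y1 - y0, x1 - x0)
            block = img[y0:y1, x0:x1]
            block[dist <= spec.break_radius_px] = spec.background_intensity

    img = np.clip(img, 0.0, 65535.0)
    return BoneImage(img, image.spacing, image.kind, image.ident)
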