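"""Ground-truthed synthetic fluorescence scenes of mitochondria and nucleoids.

The generator emulates the imaging this pipeline quantifies: tubular
mitochondria drawn as non-overlapping 2D capsules (0.3–6 um long), nucleoid
clusters as PSF-blurred Gaussian spots placed along each organelle's
midline at a Poisson rate per micrometer of organelle length, an optional
excess of forced-"empty" organelles beyond Poisson zeros, a diffuse
in-organelle background (soluble TFAM), an optional large nuclear blob
(dsDNA-dye mode), an optional cristae-like striped channel, and Poisson
followed by Gaussian camera noise. Every scene records its full ground
truth — organelle midlines, lengths, true cluster positions, true masks —
so every pipeline stage can be scored against a known answer.

Two modeling choices deserve emphasis:

* True cluster centers keep a minimum along-midline separation (default
  0.4 um, about the two-point resolvability scale of the simulated PSF).
  The counting unit is the diffraction-limited *cluster*: two emitters
  closer than the resolution limit are one cluster by definition, so a
  ground truth listing them separately would be unmeasurable in principle,
  not merely in practice. Conditional on the count, positions are uniform
  with that hard-core constraint.

* Preset empty-organelle fractions are *observed* fractions, not direct
  parameters. The forced-empty probability is calibrated in closed form so
  that forced empties plus Poisson zeros under the preset's length
  distribution give the target expected fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from ._common import InputError
from .image_io import BinaryMask, CalibratedImage


@dataclass
class SceneParams:
    """All generator knobs. Physical units in micrometers.

    length_median_um / length_sigma_log parameterize a lognormal organelle
    length distribution, clipped to length_clip_um. lambda_per_um is the
    cluster placement rate per micrometer of organelle length.
    empty_excess is the probability an organelle is forced empty beyond
    Poisson zeros. diffuse_fraction is the fraction of an organelle's
    nucleoid-channel signal emitted as uniform in-organelle background.
    poisson_scale converts intensity to expected photon counts (0 disables
    shot noise); gaussian_sd is additive read noise (0 disables).
    """

    field_um: Tuple[float, float] = (24.0, 24.0)
    pixel_size_um: float = 0.04
    n_organelles: int = 50
    length_median_um: float = 2.8
    length_sigma_log: float = 0.40
    length_clip_um: Tuple[float, float] = (0.3, 6.0)
    tube_width_um: float = 0.30
    lambda_per_um: float = 1.0
    empty_excess: float = 0.0
    spot_sigma_um: float = 0.09
    min_cluster_sep_um: float = 0.4
    diffuse_fraction: float = 0.0
    spot_amplitude: float = 800.0
    mito_amplitude: float = 500.0
    poisson_scale: float = 1.0
    gaussian_sd: float = 2.0
    nucleus: bool = False
    nucleus_diameter_um: float = 8.0
    mic60_mode: bool = False
    mic60_period_um: float = 0.25
    min_gap_um: float = 0.2
    max_place_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("pixel_size_um", "length_median_um", "length_sigma_log",
                    "tube_width_um", "lambda_per_um", "spot_sigma_um",
                    "nucleus_diameter_um", "mic60_period_um")
        for name in positive:
            if not (getattr(self, name) > 0):
                raise InputError(f"SceneParams.{name} must be > 0")
        if not (0.0 <= self.empty_excess <= 1.0):
            raise InputError("empty_excess must lie in [0, 1]")
        if not (0.0 <= self.diffuse_fraction <= 1.0):
            raise InputError("diffuse_fraction must lie in [0, 1]")
        if self.length_clip_um[0] <= 0 or self.length_clip_um[1] < self.length_clip_um[0]:
            raise InputError("length_clip_um must be a positive (lo, hi) pair")
        if self.n_organelles < 1:
            raise InputError("n_organelles must be >= 1")


@dataclass
class TrueOrganelle:
    """Ground truth for one capsule organelle."""

    label: int
    center_um: Tuple[float, float]
    theta: float
    length_um: float           # full end-to-end extent, caps included
    radius_um: float
    midline_um: np.ndarray     # (2, 2) segment endpoints, (x, y)
    cluster_t_um: np.ndarray   # positions along the midline from its start
    cluster_xy_um: np.ndarray  # (K, 2) cluster centers, (x, y)
    forced_empty: bool

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_t_um)


@dataclass
class SceneGroundTruth:
    organelles: List[TrueOrganelle]
    mito_mask: BinaryMask
    labels: np.ndarray
    nucleus_mask: Optional[BinaryMask]
    params: SceneParams

    @property
    def n_clusters(self) -> int:
        return sum(o.n_clusters for o in self.organelles)

    @property
    def cluster_xy_um(self) -> np.ndarray:
        pts = [o.cluster_xy_um for o in self.organelles if o.n_clusters]
        return np.vstack(pts) if pts else np.zeros((0, 2))


class Scene(NamedTuple):
    channels: Dict[str, CalibratedImage]
    truth: SceneGroundTruth


# ---------------------------------------------------------------------------
# closed-form empty-fraction calibration


def poisson_zero_probability(params: SceneParams) -> float:
    """P(Poisson(lambda * L) = 0) under the clipped lognormal length law.

    Evaluated by Gauss-Legendre quadrature over the standard normal
    variable; deterministic to ~1e-10.
    """
    mu = np.log(params.length_median_um)
    sig = params.length_sigma_log
    lo, hi = params.length_clip_um
    nodes, weights = np.polynomial.legendre.leggauss(400)
    z = nodes * 8.0
    w = weights * 8.0
    phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    lengths = np.clip(np.exp(mu + sig * z), lo, hi)
    return float(np.sum(w * phi * np.exp(-params.lambda_per_um * lengths)))


def expected_empty_fraction(params: SceneParams) -> float:
    """Expected observed empty fraction: forced empties plus Poisson zeros."""
    p0 = poisson_zero_probability(params)
    return params.empty_excess + (1.0 - params.empty_excess) * p0


def calibrate_empty_excess(target_fraction: float, params: SceneParams) -> float:
    """Forced-empty probability giving the target expected empty fraction."""
    p0 = poisson_zero_probability(params)
    if target_fraction < p0:
        raise InputError(
            f"target empty fraction {target_fraction} below the Poisson-zero "
            f"floor {p0:.3f} of this length distribution"
        )
    return (target_fraction - p0) / (1.0 - p0)


# ---------------------------------------------------------------------------
# presets parameterized to the quantified phenotypes

#: name -> (target empty fraction, length median, sigma_log, clip, diffuse)
_PRESETS = {
    "wt_like":        (0.13, 2.8, 0.40, (0.3, 6.0), 0.05),
    "opa1_null_like": (0.52, 1.0, 0.45, (0.3, 3.0), 0.35),
    "rescue_like":    (0.24, 1.8, 0.45, (0.3, 5.0), 0.10),
    "opa1_oe_like":   (0.10, 3.0, 0.40, (0.5, 8.0), 0.05),
    "mut_870_like":   (0.17, 2.4, 0.45, (0.5, 8.0), 0.05),
    "mut_2713_like":  (0.22, 1.8, 0.50, (0.3, 6.0), 0.05),
}


def preset_params(name: str, seed: int = 0, n_organelles: int = 50, **overrides) -> SceneParams:
    """Scene parameters for a named phenotype preset.

    Each preset fixes a length distribution and diffuse level matching the
    phenotype (fragmented and short for the null, elongated for
    overexpression) and calibrates empty_excess so the *expected* observed
    empty fraction equals the phenotype's target. The placement rate is
    1 cluster/um in every preset.
    """
    if name not in _PRESETS:
        raise InputError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(_PRESETS))}"
        )
    target, median, sigma, clip, diffuse = _PRESETS[name]
    base = SceneParams(
        n_organelles=n_organelles,
        length_median_um=median,
        length_sigma_log=sigma,
        length_clip_um=clip,
        diffuse_fraction=diffuse,
        seed=seed,
    )
    base = replace(base, **overrides)
    return replace(base, empty_excess=calibrate_empty_excess(target, base))


def preset_target_empty_fraction(name: str) -> float:
    """The empty-fraction target a preset is calibrated to."""
    if name not in _PRESETS:
        raise InputError(f"unknown preset {name!r}")
    return _PRESETS[name][0]


# ---------------------------------------------------------------------------
# sampling


def sample_lengths(params: SceneParams, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.length_clip_um
    raw = np.exp(np.log(params.length_median_um)
                 + params.length_sigma_log * rng.standard_normal(n))
    return np.clip(raw, lo, hi)


def _sample_count(params: SceneParams, length_um: float, rng: np.random.Generator) -> int:
    if params.empty_excess > 0 and rng.random() < params.empty_excess:
        return 0
    return int(rng.poisson(params.lambda_per_um * length_um))


def simulate_counts(
    params: SceneParams, n: int, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Fast truth-only sampler: (lengths, cluster counts) for n organelles.

    Uses the same length and count laws as generate_scene without placing
    geometry or rendering, for calibration and conservation checks.
    """
    rng = rng or np.random.default_rng(params.seed)
    lengths = sample_lengths(params, n, rng)
    counts = np.array([_sample_count(params, L, rng) for L in lengths])
    return lengths, counts


def _place_positions(
    m: float, k: int, sep: float, rng: np.random.Generator
) -> np.ndarray:
    """k positions on [0, m] with pairwise separation >= sep.

    Exact hard-core sampler: draw k uniforms on the shrunken interval,
    sort, and re-expand. k is reduced when the midline cannot hold it.
    """
    if k <= 0:
        return np.zeros(0)
    if m <= 0:
        return np.zeros(1)  # blob-like organelle: a single central cluster
    k = min(k, int(np.floor(m / sep)) + 1)
    slack = m - (k - 1) * sep
    u = np.sort(rng.uniform(0.0, slack, size=k))
    return u + sep * np.arange(k)


def _seg_seg_dist(p0, p1, q0, q1) -> float:
    """Minimum distance between 2D segments p0-p1 and q0-q1."""
    def pt_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        return float(np.linalg.norm(p - (a + t * ab)))

    d = p1 - p0
    e = q1 - q0
    r = p0 - q0
    a, b_, c = float(d @ d), float(d @ e), float(e @ e)
    f, g = float(d @ r), float(e @ r)
    denom = a * c - b_ * b_
    if denom > 1e-12:
        s = np.clip((b_ * g - c * f) / denom, 0.0, 1.0)
        t = np.clip((a * g - b_ * f) / denom, 0.0, 1.0)
        cand = float(np.linalg.norm((p0 + s * d) - (q0 + t * e)))
    else:
        cand = np.inf
    return min(cand, pt_seg(p0, q0, q1), pt_seg(p1, q0, q1),
               pt_seg(q0, p0, p1), pt_seg(q1, p0, p1))


def _place_organelles(params: SceneParams, rng: np.random.Generator) -> List[TrueOrganelle]:
    fw, fh = params.field_um
    r = params.tube_width_um / 2.0
    margin = r + params.min_gap_um
    sep_needed = params.tube_width_um + params.min_gap_um
    placed: List[TrueOrganelle] = []
    segments: List[Tuple[np.ndarray, np.ndarray]] = []

    lengths = sample_lengths(params, params.n_organelles, rng)
    for i, L in enumerate(lengths, start=1):
        half = max(L / 2.0 - r, 0.0)
        ok = False
        for _ in range(params.max_place_tries):
            theta = rng.uniform(0, np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])
            ext = half * np.abs(u) + margin
            if ext[0] >= fw - ext[0] or ext[1] >= fh - ext[1]:
                continue  # does not fit the field at this orientation
            cx = rng.uniform(ext[0], fw - ext[0])
            cy = rng.uniform(ext[1], fh - ext[1])
            c = np.array([cx, cy])
            p0, p1 = c - half * u, c + half * u
            if all(_seg_seg_dist(p0, p1, q0, q1) >= sep_needed for q0, q1 in segments):
                ok = True
                break
        if not ok:
            raise InputError(
                f"could not place organelle {i}/{params.n_organelles} without "
                f"overlap after {params.max_place_tries} tries; lower the "
                f"organelle density or enlarge the field"
            )
        segments.append((p0, p1))

        forced = params.empty_excess > 0 and rng.random() < params.empty_excess
        k = 0 if forced else int(rng.poisson(params.lambda_per_um * L))
        m = 2.0 * half
        t = _place_positions(m, k, params.min_cluster_sep_um, rng) if k else np.zeros(0)
        xy = p0[None, :] + t[:, None] * u[None, :] if len(t) else np.zeros((0, 2))
        placed.append(
            TrueOrganelle(
                label=i, center_um=(cx, cy), theta=float(theta), length_um=float(L),
                radius_um=r, midline_um=np.vstack([p0, p1]), cluster_t_um=t,
                cluster_xy_um=xy, forced_empty=bool(forced),
            )
        )
    return placed


# ---------------------------------------------------------------------------
# rendering


def _capsule_pixels(org: TrueOrganelle, xs: np.ndarray, ys: np.ndarray, pad_um: float):
    """(row_slice, col_slice, interior mask, axial coordinate) in a bbox."""
    p0, p1 = org.midline_um
    r = org.radius_um + pad_um
    lo = np.minimum(p0, p1) - r
    hi = np.maximum(p0, p1) + r
    c0 = max(0, np.searchsorted(xs, lo[0]) - 1)
    c1 = min(len(xs), np.searchsorted(xs, hi[0]) + 1)
    r0 = max(0, np.searchsorted(ys, lo[1]) - 1)
    r1 = min(len(ys), np.searchsorted(ys, hi[1]) + 1)
    gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        t = np.zeros_like(gx)
        proj_x, proj_y = np.full_like(gx, p0[0]), np.full_like(gy, p0[1])
        axial = np.zeros_like(gx)
    else:
        t = np.clip(((gx - p0[0]) * d[0] + (gy - p0[1]) * d[1]) / denom, 0.0, 1.0)
        proj_x = p0[0] + t * d[0]
        proj_y = p0[1] + t * d[1]
        axial = t * np.sqrt(denom)
    dist = np.sqrt((gx - proj_x) ** 2 + (gy - proj_y) ** 2)
    return slice(r0, r1), slice(c0, c1), dist <= r, axial


def _add_spot(img: np.ndarray, xs, ys, x0, y0, amp, sigma):
    px = xs[1] - xs[0] if len(xs) > 1 else 1.0
    rad = 4.0 * sigma
    c0 = max(0, np.searchsorted(xs, x0 - rad) - 1)
    c1 = min(len(xs), np.searchsorted(xs, x0 + rad) + 1)
    r0 = max(0, np.searchsorted(ys, y0 - rad) - 1)
    r1 = min(len(ys), np.searchsorted(ys, y0 + rad) + 1)
    gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
    img[r0:r1, c0:c1] += amp * np.exp(
        -((gx - x0) ** 2 + (gy - y0) ** 2) / (2.0 * sigma**2)
    )


def generate_scene(params: SceneParams, render: bool = True) -> Scene:
    """Generate one scene: per-channel calibrated images plus ground truth.

    Deterministic given params.seed. With render=False only the geometric
    and count truth is produced (channels empty), which is much faster for
    statistical checks that do not need pixels.
    """
    rng = np.random.default_rng(params.seed)
    organelles = _place_organelles(params, rng)
    px = params.pixel_size_um
    W = int(round(params.field_um[0] / px))
    H = int(round(params.field_um[1] / px))
    xs = np.arange(W) * px
    ys = np.arange(H) * px

    labels = np.zeros((H, W), dtype=np.int32)
    for org in organelles:
        rs, cs, inside, _ = _capsule_pixels(org, xs, ys, 0.0)
        labels[rs, cs][inside] = org.label
    mito_mask = BinaryMask(labels > 0, px, provenance="detection")

    nucleus_mask = None
    nucleus_center = None
    if params.nucleus:
        nr = params.nucleus_diameter_um / 2.0
        nucleus_center = (
            rng.uniform(nr, params.field_um[0] - nr),
            rng.uniform(nr, params.field_um[1] - nr),
        )
        gx, gy = np.meshgrid(xs, ys)
        ndisk = (gx - nucleus_center[0]) ** 2 + (gy - nucleus_center[1]) ** 2 <= nr**2
        nucleus_mask = BinaryMask(ndisk, px, provenance="detection")

    truth = SceneGroundTruth(
        organelles=organelles, mito_mask=mito_mask, labels=labels,
        nucleus_mask=nucleus_mask, params=params,
    )
    if not render:
        return Scene(channels={}, truth=truth)

    mito = np.zeros((H, W))
    mito[mito_mask.pixels] = params.mito_amplitude
    mito = ndi.gaussian_filter(mito, sigma=1.0)

    nucleoid = np.zeros((H, W))
    spot_integral = params.spot_amplitude * 2.0 * np.pi * (params.spot_sigma_um / px) ** 2
    for org in organelles:
        for (x0, y0) in org.cluster_xy_um:
            _add_spot(nucleoid, xs, ys, x0, y0, params.spot_amplitude,
                      params.spot_sigma_um)
        if params.diffuse_fraction > 0:
            rs, cs, inside, _ = _capsule_pixels(org, xs, ys, 0.0)
            area_px = int(inside.sum())
            if area_px == 0:
                continue
            f = params.diffuse_fraction
            signal = org.n_clusters * spot_integral
            if signal == 0:  # empty organelle still leaks soluble protein
                signal = params.lambda_per_um * org.length_um * spot_integral
            level = (f / (1.0 - f)) * signal / area_px if f < 1 else signal / area_px
            patch = nucleoid[rs, cs]
            patch[inside] += level
            nucleoid[rs, cs] = patch

    if params.nucleus:
        gx, gy = np.meshgrid(xs, ys)
        nr = params.nucleus_diameter_um / 2.0
        blob = np.where(
            (gx - nucleus_center[0]) ** 2 + (gy - nucleus_center[1]) ** 2 <= nr**2,
            0.6 * params.spot_amplitude, 0.0,
        )
        nucleoid += ndi.gaussian_filter(blob, sigma=0.5 / px)

    channels = {"mito": mito, "nucleoid": nucleoid}
    if params.mic60_mode:
        mic = np.zeros((H, W))
        for org in organelles:
            rs, cs, inside, axial = _capsule_pixels(org, xs, ys, 0.0)
            stripes = 0.5 + 0.5 * np.cos(2.0 * np.pi * axial / params.mic60_period_um)
            patch = mic[rs, cs]
            patch[inside] += params.mito_amplitude * stripes[inside]
            mic[rs, cs] = patch
        channels["mic60"] = ndi.gaussian_filter(mic, sigma=1.0)

    out = {}
    for name, img in channels.items():
        noisy = img
        if params.poisson_scale > 0:
            noisy = rng.poisson(np.maximum(noisy, 0.0) * params.poisson_scale)
            noisy = noisy.astype(np.float64) / params.poisson_scale
        if params.gaussian_sd > 0:
            noisy = noisy + rng.normal(0.0, params.gaussian_sd, size=noisy.shape)
        out[name] = CalibratedImage(
            pixels=np.maximum(noisy, 0.0), pixel_size_um=px, channel=name,
            meta={"seed": params.seed},
        )
    return Scene(channels=out, truth=truth)


# ---------------------------------------------------------------------------
# scoring


def score_detection(
    clusters,
    organelle_records,
    truth: SceneGroundTruth,
    match_radius_um: float = 0.2,
) -> Dict[str, float]:
    """Score detected clusters and organelles against scene ground truth.

    Cluster matching is greedy by ascending centroid distance, one-to-one,
    within match_radius_um; unmatched detections are false positives and
    unmatched truth clusters false negatives. Organelles are matched by
    nearest centroid; per-organelle count and length errors are summarized.
    """
    if abs(truth.mito_mask.pixel_size_um - truth.params.pixel_size_um) > 1e-9:
        raise InputError("truth calibration inconsistent")
    det_xy = np.array([c.centroid_um for c in clusters]) if clusters else np.zeros((0, 2))
    true_xy = truth.cluster_xy_um

    matches = 0
    if len(det_xy) and len(true_xy):
        from scipy.spatial import cKDTree

        tree = cKDTree(true_xy)
        pairs = []
        dists, idxs = tree.query(det_xy, k=min(len(true_xy), 4),
                                 distance_upper_bound=match_radius_um)
        dists = np.atleast_2d(dists)
        idxs = np.atleast_2d(idxs)
        for di in range(len(det_xy)):
            for dd, ti in zip(dists[di], idxs[di]):
                if np.isfinite(dd) and ti < len(true_xy):
                    pairs.append((float(dd), di, int(ti)))
        pairs.sort()
        used_d, used_t = set(), set()
        for dd, di, ti in pairs:
            if di in used_d or ti in used_t:
                continue
            used_d.add(di)
            used_t.add(ti)
            matches += 1

    n_det, n_true = len(det_xy), len(true_xy)
    precision = matches / n_det if n_det else (1.0 if n_true == 0 else 0.0)
    recall = matches / n_true if n_true else 1.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0

    # organelle-level matching by centroid proximity
    count_errors, length_errors = [], []
    if organelle_records and truth.organelles:
        det_cent = np.array([o.centroid_um for o in organelle_records])
        for torg in truth.organelles:
            d2 = ((det_cent - np.asarray(torg.center_um)) ** 2).sum(axis=1)
            j = int(np.argmin(d2))
            if np.sqrt(d2[j]) <= max(torg.length_um / 2.0, 0.5):
                rec = organelle_records[j]
                if rec.cluster_count is not None:
                    count_errors.append(abs(rec.cluster_count - torg.n_clusters))
                length_errors.append(abs(rec.length_um - torg.length_um))

    return {
        "n_true_clusters": n_true,
        "n_detected_clusters": n_det,
        "n_matched": matches,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_true_organelles": len(truth.organelles),
        "n_detected_organelles": len(organelle_records),
        "organelle_count_error": abs(len(organelle_records) - len(truth.organelles)),
        "mean_cluster_count_error": float(np.mean(count_errors)) if count_errors else 0.0,
        "mean_length_error_um": float(np.mean(length_errors)) if length_errors else 0.0,
        "max_length_error_um": float(np.max(length_errors)) if length_errors else 0.0,
    }
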