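"""Measurement stack: myocardial segmentation, noise (CoV), regional SSIM,
polar maps, normal databases, total perfusion deficit, ROC/AUC with DeLong
tests, and paired t-tests.

The similarity index is the whole-region, constant-free form

    SSIM = (2 mu_f mu_r / (mu_f^2 + mu_r^2)) * (2 cov_fr / (var_f + var_r))

with ``f`` the full-time reference and ``r`` the reduced-time or denoised
image, all statistics taken over the segmented myocardium with sample
(n-1) normalization.  Its maximum is 1.0, attained exactly when the two
regions are identical.

TPD reduces a polar map to a single abnormality percentage against a
normal database: per sample ``z = (mean_db - value) / sd_db``, the deficit
is ``clip(z - z0, 0, zcap) / zcap`` (hypoperfusion threshold ``z0 = 3``,
severity cap ``zcap = 4``), and TPD is 100 x the mean deficit — a combined
extent-and-severity score used as the observer rating for ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volume import Volume

__all__ = [
    "RegionStats", "PolarMap", "NormalDB", "RatingSet", "AUCResult",
    "segment_myocardium", "cov", "ssim_region", "region_stats", "polar_map",
    "build_normal_db", "tpd", "roc_auc", "delong_test", "paired_t_test",
]


# --------------------------------------------------------------------------
# region statistics, CoV, SSIM

@dataclass(frozen=True)
class RegionStats:
    """First/second moments of the reference (f) and test (r) regions."""

    mu_f: float
    mu_r: float
    var_f: float
    var_r: float
    cov_fr: float


def segment_myocardium(
    vol: Volume,
    mode: str = "threshold",
    truth_mask: Volume | None = None,
    threshold_fraction: float = 0.5,
    local_fraction: float = 0.75,
    n_sectors: int = 72,
    slice_fraction: float = 0.9,
    apex_centre_fraction: float = 0.85,
    max_half_wall_mm: float = 9.0,
) -> Volume:
    """Outline the left myocardium.

    ``truth`` mode passes the phantom mask through.  ``threshold`` mode is a
    simplified LV wall tracker: voxels above ``threshold_fraction`` of the
    robust maximum (99th percentile) form a candidate blob (largest
    connected component); within each short-axis slice whose peak reaches
    ``slice_fraction`` of the robust maximum, radial profiles about the blob
    axis are walked per angular sector and only voxels near the profile peak
    (above ``local_fraction`` of the sector peak and within
    ``max_half_wall_mm`` of the peak radius) are kept.  Slices without a
    resolved cavity (centre value close to the slice peak) are treated as
    apex caps and kept whole.  This follows the ridge of the blurred wall
    rather than its 50 % isocontour, so the outline stays on the myocardium
    instead of swallowing the cavity.
    """
    if mode == "truth":
        if truth_mask is None:
            raise ValueError("truth mode requires a truth mask")
        return truth_mask
    if mode != "threshold":
        raise ValueError(f"unknown segmentation mode {mode!r}")
    data = vol.data
    robust_max = np.percentile(data, 99)
    if robust_max <= 0:
        raise ValueError("cannot segment an all-zero volume")
    blob = data >= threshold_fraction * robust_max
    labels, n = ndimage.label(blob)
    if n == 0:
        raise ValueError("empty segmentation")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    blob = labels == (1 + int(np.argmax(sizes)))

    idx = np.argwhere(blob)
    cx, cy = idx[:, 0].mean(), idx[:, 1].mean()
    nx, ny, nz = data.shape
    xg, yg = np.meshgrid(np.arange(nx) - cx, np.arange(ny) - cy, indexing="ij")
    radius = np.sqrt(xg**2 + yg**2)
    sector = (
        (np.degrees(np.arctan2(yg, xg)) % 360.0) / (360.0 / n_sectors)
    ).astype(np.int64)
    w_max = max_half_wall_mm / vol.voxel_mm

    keep = np.zeros_like(blob)
    ci, cj = int(round(cx)), int(round(cy))
    for z in range(nz):
        bz = blob[:, :, z]
        if not bz.any():
            continue
        dz = data[:, :, z]
        if dz.max() < slice_fraction * robust_max:
            continue  # apical/basal spill-over slice
        ii, jj = np.nonzero(bz)
        vals = dz[ii, jj]
        if dz[ci, cj] >= apex_centre_fraction * vals.max():
            keep[:, :, z] |= bz  # filled apex cap: no cavity to exclude
            continue
        rr, aa = radius[ii, jj], sector[ii, jj]
        order = np.argsort(aa, kind="stable")
        ii, jj, vals, rr, aa = ii[order], jj[order], vals[order], rr[order], aa[order]
        bounds = np.searchsorted(aa, np.arange(n_sectors + 1))
        for s in range(n_sectors):
            lo, hi = bounds[s], bounds[s + 1]
            if lo == hi:
                continue
            v, r = vals[lo:hi], rr[lo:hi]
            pk = int(np.argmax(v))
            sel = (v >= local_fraction * v[pk]) & (np.abs(r - r[pk]) <= w_max)
            keep[ii[lo:hi][sel], jj[lo:hi][sel], z] = True
    if not keep.any():
        raise ValueError("empty segmentation")
    # drop stray islands (e.g. hot noise voxels on skipped slices)
    labels, n = ndimage.label(keep)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        keep = labels == (1 + int(np.argmax(sizes)))
    return vol.like(keep.astype(np.float64))


def _masked(vol: Volume, mask: Volume) -> np.ndarray:
    if mask.shape != vol.shape:
        raise ValueError("mask grid does not match volume grid")
    m = mask.data > 0
    if not m.any():
        raise ValueError("mask is empty")
    return vol.data[m]


def cov(vol: Volume, mask: Volume) -> float:
    """Coefficient of variation, 100 x sd / mean of masked voxels
    (sample sd, n-1)."""
    vals = _masked(vol, mask)
    mean = vals.mean()
    if mean == 0:
        raise ValueError("region mean is zero; CoV undefined")
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return float(100.0 * sd / mean)


def region_stats(full: Volume, other: Volume, mask: Volume) -> RegionStats:
    f = _masked(full, mask)
    r = _masked(other, mask)
    mu_f, mu_r = f.mean(), r.mean()
    df, dr = f - mu_f, r - mu_r
    n = len(f)
    if n < 2:
        raise ValueError("region needs at least 2 voxels for (co)variances")
    return RegionStats(
        mu_f=float(mu_f), mu_r=float(mu_r),
        var_f=float((df * df).sum() / (n - 1)),
        var_r=float((dr * dr).sum() / (n - 1)),
        cov_fr=float((df * dr).sum() / (n - 1)),
    )


def ssim_region(full: Volume, other: Volume, mask: Volume) -> float:
    """Single-value, constant-free SSIM over the masked region (max 1.0,
    attained iff the regions are identical)."""
    s = region_stats(full, other, mask)
    lum_den = s.mu_f * s.mu_f + s.mu_r * s.mu_r
    str_den = s.var_f + s.var_r
    if lum_den == 0:
        raise ValueError("SSIM undefined: both region means are zero")
    if str_den == 0:
        raise ValueError("SSIM undefined: both region variances are zero")
    return float((2.0 * (s.mu_f * s.mu_r) / lum_den) * (2.0 * s.cov_fr / str_den))


# --------------------------------------------------------------------------
# polar maps, normal database, TPD

@dataclass
class PolarMap:
    """Myocardial samples on an (apex->base ring) x (angular sector) grid,
    normalized to the map's own mean."""

    samples: np.ndarray  # [n_rings, n_angles]
    norm_factor: float

    @property
    def n_rings(self) -> int:
        return self.samples.shape[0]

    @property
    def n_angles(self) -> int:
        return self.samples.shape[1]


def polar_map(
    vol: Volume,
    mask: Volume,
    n_rings: int = 12,
    n_angles: int = 36,
    missing_tolerance: float = 0.05,
) -> PolarMap:
    """Sample the myocardium into a bull's-eye grid.

    For each short-axis level (apex ring included) and angular sector the
    sample is the maximum count along the radial ray inside the mask
    (nearest-voxel ray marching, so each sample is an actual count).  Rays that miss
    the mask are imputed from their angular neighbours; if more than
    ``missing_tolerance`` of all rays miss, the map is rejected.
    The map is normalized by its own mean, making it invariant to global
    intensity scaling.
    """
    m = mask.data > 0
    if not m.any():
        raise ValueError("mask is empty")
    if vol.shape != mask.shape:
        raise ValueError("volume and mask grids differ")

    idx = np.argwhere(m)
    cx, cy = idx[:, 0].mean(), idx[:, 1].mean()
    z_lo, z_hi = idx[:, 2].min() + 0.5, idx[:, 2].max() - 0.5
    if z_hi <= z_lo:
        z_lo, z_hi = idx[:, 2].min(), idx[:, 2].max()
    z_levels = np.linspace(z_lo, z_hi, n_rings)
    angles = np.deg2rad(np.arange(n_angles) * (360.0 / n_angles))
    r_max = max(vol.shape[0], vol.shape[1]) / 2.0
    radii = np.arange(0.0, r_max, 0.4)

    # ray lattice: [n_angles, n_radii] points per z level
    dx = np.cos(angles)[:, None] * radii[None, :]
    dy = np.sin(angles)[:, None] * radii[None, :]

    samples = np.full((n_rings, n_angles), np.nan)
    mask_f = m.astype(np.float64)
    for ri, zl in enumerate(z_levels):
        coords = np.stack(
            [cx + dx, cy + dy, np.full_like(dx, zl)], axis=0
        ).reshape(3, -1)
        # nearest-voxel sampling: the profile maximum is an actual voxel count
        vals = ndimage.map_coordinates(vol.data, coords, order=0, mode="constant")
        ms = ndimage.map_coordinates(mask_f, coords, order=0, mode="constant")
        vals = vals.reshape(n_angles, len(radii))
        ms = ms.reshape(n_angles, len(radii))
        inside = ms >= 0.5
        hit = inside.any(axis=1)
        row = np.where(hit, np.where(inside, vals, -np.inf).max(axis=1), np.nan)
        samples[ri] = row

    missing = np.isnan(samples)
    if missing.mean() > missing_tolerance:
        raise ValueError(
            f"{missing.mean():.0%} of polar-map rays miss the myocardium "
            f"(tolerance {missing_tolerance:.0%})"
        )
    if missing.any():
        for ri in range(n_rings):
            row = samples[ri]
            bad = np.isnan(row)
            if bad.all():
                raise ValueError(f"polar-map ring {ri} has no myocardial samples")
            if bad.any():
                good = np.where(~bad)[0]
                for a in np.where(bad)[0]:
                    d = np.minimum((good - a) % n_angles, (a - good) % n_angles)
                    near = good[d == d.min()]
                    row[a] = row[near].mean()

    norm = samples.mean()
    if norm <= 0:
        raise ValueError("polar map mean is non-positive")
    return PolarMap(samples / norm, float(norm))


@dataclass
class NormalDB:
    """Per-sample mean and sd of normal-study polar maps."""

    mean: np.ndarray
    sd: np.ndarray
    n_studies: int
    arm: str = ""
    acquisition_time: str = ""
    method: str = ""

    SD_FLOOR_FRACTION = 0.01


def build_normal_db(
    maps: list[PolarMap],
    arm: str = "",
    acquisition_time: str = "",
    method: str = "",
) -> NormalDB:
    """Per-sample mean/sd (n-1) across >= 2 normal maps; sd floored at 1 %
    of the mean map level to keep z-scores finite."""
    if len(maps) < 2:
        raise ValueError("a normal database needs at least 2 studies")
    shape = maps[0].samples.shape
    if any(mp.samples.shape != shape for mp in maps):
        raise ValueError("polar-map grids differ")
    stack = np.stack([mp.samples for mp in maps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    floor = NormalDB.SD_FLOOR_FRACTION * mean.mean()
    return NormalDB(
        mean=mean, sd=np.maximum(sd, floor), n_studies=len(maps),
        arm=arm, acquisition_time=acquisition_time, method=method,
    )


def tpd(map_: PolarMap, db: NormalDB, z0: float = 3.0, zcap: float = 4.0) -> float:
    """Total perfusion deficit (percent) of one study against a normal DB."""
    if map_.samples.shape != db.mean.shape:
        raise ValueError("polar map and normal DB grids differ")
    if z0 < 0 or zcap <= 0:
        raise ValueError("need z0 >= 0 and zcap > 0")
    z = (db.mean - map_.samples) / db.sd
    deficit = np.clip(z - z0, 0.0, zcap) / zcap
    return float(100.0 * deficit.mean())


# --------------------------------------------------------------------------
# ROC / AUC / DeLong / paired t

@dataclass
class RatingSet:
    """Observer ratings (here: TPD scores) with defect-presence truth."""

    scores: np.ndarray
    truth: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.scores.shape != self.truth.shape:
            raise ValueError("scores and truth must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ratings must be finite")


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float
    n_pos: int
    n_neg: int


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-positive and per-negative mean of the
    Mann-Whitney kernel (ties count 1/2)."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0)


def roc_auc(ratings: RatingSet) -> AUCResult:
    """AUC as the Mann-Whitney statistic; standard error by DeLong."""
    pos = ratings.scores[ratings.truth]
    neg = ratings.scores[~ratings.truth]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs both defect and normal studies")
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    se = float(np.sqrt(s10 / len(pos) + s01 / len(neg)))
    return AUCResult(auc=auc, se=se, n_pos=len(pos), n_neg=len(neg))


def delong_test(ratings_a: RatingSet, ratings_b: RatingSet) -> tuple[float, float, float]:
    """DeLong's test for two correlated AUCs measured on the same studies.

    Returns ``(delta_auc, z, p)`` with a two-sided normal p-value.  The
    covariance of the paired AUCs comes from the placement values, so the
    internal AUCs equal :func:`roc_auc` exactly.
    """
    if len(ratings_a.scores) != len(ratings_b.scores) or np.any(
        ratings_a.truth != ratings_b.truth
    ):
        raise ValueError("DeLong test requires paired ratings on identical studies")
    truth = ratings_a.truth
    pos_a, neg_a = ratings_a.scores[truth], ratings_a.scores[~truth]
    pos_b, neg_b = ratings_b.scores[truth], ratings_b.scores[~truth]
    if len(pos_a) == 0 or len(neg_a) == 0:
        raise ValueError("ROC needs both classes")
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(pos_a), len(neg_a)

    def _cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1]) if len(u) > 1 else 0.0

    var = (
        (_cov(v10a, v10a) + _cov(v10b, v10b) - 2 * _cov(v10a, v10b)) / m
        + (_cov(v01a, v01a) + _cov(v01b, v01b) - 2 * _cov(v01a, v01b)) / n
    )
    delta = float(auc_a - auc_b)
    if var <= 0:
        return delta, 0.0, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return delta, float(z), p


def paired_t_test(x, y) -> tuple[float, float]:
    """Paired t-test on the differences ``x - y``.

    All-zero differences give ``(0, 1)``; zero-variance nonzero-mean
    differences are degenerate and give ``(+/-inf, 0)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = float(2.0 * stats.t.sf(abs(t), df=len(d) - 1))
    return float(t), p
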