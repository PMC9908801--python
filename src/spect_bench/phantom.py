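"""Digital left-ventricle phantom and gated acquisition simulator.

This module is the data source for the whole benchmark.  It emulates gated
99mTc myocardial-perfusion SPECT studies: a short-axis-aligned LV
half-ellipsoid shell (apex toward ``-z``) with uniform myocardial uptake
inside a soft-tissue body cylinder, projected through the attenuated
system model and split into independent Poisson-sampled cardiac gates.
Reduced acquisition times are obtained afterwards by summing a random
subset of gates per projection, exactly the resampling scheme used to
emulate shorter scans from gated clinical data.

Inter-"patient" variability comes from the seed, which perturbs LV axes and
position by up to +/-10 %.  Cardiac motion is deliberately not modelled:
gates are i.i.d. realizations of the same mean projections, so gate summing
differs from a longer scan only through which Poisson draws are combined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .geometry import SystemGeometry
from .projector import ProjectionSet, forward_project
from .volume import AttenuationMap, Volume, save_volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "GatedProjectionSet",
    "DefectVOI",
    "make_phantom",
    "simulate_gated_acquisition",
    "sum_gates",
    "make_defect_voi",
    "STRESS_TOTAL_COUNTS",
    "REST_TOTAL_COUNTS",
]

# Default stress/rest grand totals (counts per acquisition).  The 1:3 ratio
# mirrors typical 250/750 MBq one-day protocol dosing; absolute levels are
# set so full-time reconstructions land at clinically plausible myocardial
# noise (CoV roughly in the low-twenties percent range).
STRESS_TOTAL_COUNTS = 4.0e5
REST_TOTAL_COUNTS = 1.2e6

SOFT_TISSUE_MU = 0.15  # 1/cm at 140 keV


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and activity description of one synthetic "patient".

    Semi-axes are in mm; ``endo`` is the cavity boundary, ``epi`` the outer
    wall, so the wall thickness per axis is ``epi - endo``.  ``seed``
    perturbs axes and LV position by up to ``jitter`` (fractional).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 4.8
    endo_mm: tuple[float, float, float] = (24.0, 24.0, 36.0)
    epi_mm: tuple[float, float, float] = (34.0, 34.0, 46.0)
    myo_activity: float = 1.0
    background_fraction: float = 0.1
    body_mm: tuple[float, float] = (130.0, 95.0)
    mu_cm: float = SOFT_TISSUE_MU
    jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(ep <= en for en, ep in zip(self.endo_mm, self.epi_mm)):
            raise ValueError("epi semi-axes must exceed endo semi-axes")
        if self.myo_activity < 0 or self.background_fraction < 0:
            raise ValueError("activities must be non-negative")
        if self.mu_cm < 0:
            raise ValueError("mu must be non-negative")

    @staticmethod
    def desk(seed: int = 0, grid: int = 48, **kw) -> "PhantomSpec":
        """Desk-scale spec: smaller grid, body shrunk to fit the field of view."""
        return PhantomSpec(
            grid_shape=(grid, grid, grid), body_mm=(95.0, 75.0), seed=seed, **kw
        )


@dataclass
class PhantomTruth:
    """Ground-truth bundle: activity, attenuation, myocardium mask, spec."""

    activity: Volume
    attn: AttenuationMap
    myo_mask: Volume
    spec: PhantomSpec
    centre_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes_mm: tuple[tuple[float, ...], tuple[float, ...]] = ((0,) * 3, (0,) * 3)

    def save(self, prefix: str) -> None:
        """Write activity/mu/mask NIfTIs plus a JSON spec sidecar."""
        save_volume(self.activity, f"{prefix}_activity.nii.gz")
        save_volume(self.attn.mu, f"{prefix}_mu.nii.gz")
        save_volume(self.myo_mask, f"{prefix}_mask.nii.gz")
        with open(f"{prefix}_spec.json", "w") as f:
            json.dump(asdict(self.spec), f, indent=1)


@dataclass
class GatedProjectionSet:
    """Integer count projections split into cardiac gates,
    ``gates[gate, view, det_row, det_col]``."""

    gates: np.ndarray
    geometry: SystemGeometry

    def __post_init__(self) -> None:
        self.gates = np.asarray(self.gates)
        if self.gates.ndim != 4 or self.gates.shape[0] < 1:
            raise ValueError("gates must be a [n_gates, n_views, rows, cols] stack")
        expected = (self.geometry.n_views, self.geometry.det_rows, self.geometry.det_cols)
        if self.gates.shape[1:] != expected:
            raise ValueError("gate stack inconsistent with geometry")
        if np.any(self.gates < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.gates.dtype, np.integer):
            if not np.allclose(self.gates, np.round(self.gates)):
                raise ValueError("gate counts must be integral")
            self.gates = self.gates.astype(np.int64)

    @property
    def n_gates(self) -> int:
        return self.gates.shape[0]

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("gates", data=self.gates)
            g = self.geometry
            for key in (
                "n_views", "arc_deg", "det_rows", "det_cols",
                "pixel_mm", "radius_mm", "psf_sigma0_mm", "psf_slope",
            ):
                d.attrs[key] = getattr(g, key)


@dataclass
class DefectVOI:
    """Binary perfusion-defect mask in the short-axis frame.

    ``severity`` is the fractional count reduction applied inside the mask
    (presets: shallow 0.4, deep 0.7).  ``location`` labels the wall segment
    of the sector centre; ``extent_deg`` / ``extent_z`` record the drawn
    sector size for auditability.
    """

    mask: Volume
    severity: float
    location: str
    extent_deg: float = 0.0
    extent_z_fraction: float = 0.0

    SHALLOW = 0.4
    DEEP = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.severity <= 1.0):
            raise ValueError("severity must lie in (0, 1]")
        if not self.mask.data.any():
            raise ValueError("defect mask is empty")


def _mm_grids(spec: PhantomSpec, centre_mm: np.ndarray):
    nx, ny, nz = spec.grid_shape
    cx = (np.arange(nx) - (nx - 1) / 2.0) * spec.voxel_mm
    cy = (np.arange(ny) - (ny - 1) / 2.0) * spec.voxel_mm
    cz = (np.arange(nz) - (nz - 1) / 2.0) * spec.voxel_mm
    x, y, z = np.meshgrid(cx - centre_mm[0], cy - centre_mm[1], cz - centre_mm[2],
                          indexing="ij")
    return x, y, z


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Voxelize one seeded LV phantom.

    The myocardium is the half-shell between the endo and epi ellipsoids on
    the apical side (``z <= 0`` of the LV frame), whose analytic volume is
    ``(2/3) * pi * (a2 b2 c2 - a1 b1 c1)``.  Background activity fills the
    body cylinder at ``background_fraction`` of the myocardial level;
    attenuation is uniform soft tissue inside the body.
    """
    rng = np.random.default_rng(spec.seed)
    j = spec.jitter
    endo0 = np.asarray(spec.endo_mm)
    epi0 = np.asarray(spec.epi_mm)
    # jitter the mid-wall surface and the wall thickness separately, so
    # "patients" vary in chamber size without nonphysiologic wall extremes
    mid = 0.5 * (endo0 + epi0) * rng.uniform(1 - j, 1 + j, 3)
    half_wall = 0.5 * (epi0 - endo0) * rng.uniform(1 - j, 1 + j, 3)
    endo = mid - half_wall
    epi = mid + half_wall
    if np.any(epi <= endo) or np.any(endo <= 0):
        raise ValueError("wall thickness <= 0 after seed perturbation")
    centre = rng.uniform(-j, j, 3) * epi0

    x, y, z = _mm_grids(spec, centre)
    r_endo = (x / endo[0]) ** 2 + (y / endo[1]) ** 2 + (z / endo[2]) ** 2
    r_epi = (x / epi[0]) ** 2 + (y / epi[1]) ** 2 + (z / epi[2]) ** 2
    myo = (r_epi <= 1.0) & (r_endo >= 1.0) & (z <= 0.0)

    xb, yb, _ = _mm_grids(spec, np.zeros(3))
    body = (xb / spec.body_mm[0]) ** 2 + (yb / spec.body_mm[1]) ** 2 <= 1.0

    activity = np.where(body, spec.background_fraction * spec.myo_activity, 0.0)
    activity[myo] = spec.myo_activity
    mu = np.where(body, spec.mu_cm, 0.0)

    vox = spec.voxel_mm
    return PhantomTruth(
        activity=Volume(activity, vox),
        attn=AttenuationMap(Volume(mu, vox)),
        myo_mask=Volume(myo.astype(np.float64), vox),
        spec=spec,
        centre_mm=tuple(centre),
        axes_mm=(tuple(endo), tuple(epi)),
    )


def simulate_gated_acquisition(
    phantom: PhantomTruth,
    geom: SystemGeometry,
    total_counts: float = STRESS_TOTAL_COUNTS,
    n_gates: int = 8,
    seed: int = 0,
) -> GatedProjectionSet:
    """Project the phantom and sample independent Poisson gates.

    The noise-free projections are scaled so their grand total equals
    ``total_counts``, split evenly across ``n_gates`` gates, and each gate
    drawn as an independent Poisson realization.
    """
    if total_counts < 0:
        raise ValueError("total_counts must be non-negative")
    if n_gates < 1:
        raise ValueError("n_gates must be >= 1")
    clean = forward_project(phantom.activity, phantom.attn, geom).counts
    s = clean.sum()
    lam = np.zeros_like(clean) if (s == 0 or total_counts == 0) else clean * (
        total_counts / s / n_gates
    )
    rng = np.random.default_rng(seed)
    gates = rng.poisson(lam, size=(n_gates,) + lam.shape)
    return GatedProjectionSet(gates, geom)


def sum_gates(gated: GatedProjectionSet, n_select: int, seed: int = 0) -> ProjectionSet:
    """Emulate a reduced acquisition time by summing ``n_select`` gates.

    For every projection view independently, ``n_select`` distinct gate
    indices are drawn uniformly at random and summed.  Selecting all gates
    reproduces the full-time projection set exactly, independent of seed.
    """
    ng = gated.n_gates
    if not (1 <= n_select <= ng):
        raise ValueError(f"n_select must lie in [1, {ng}]")
    if n_select == ng:
        counts = gated.gates.sum(axis=0)
    else:
        rng = np.random.default_rng(seed)
        counts = np.empty(gated.gates.shape[1:], dtype=np.int64)
        for v in range(gated.geometry.n_views):
            pick = rng.choice(ng, size=n_select, replace=False)
            counts[v] = gated.gates[pick, v].sum(axis=0)
    return ProjectionSet(counts.astype(np.float64), gated.geometry)


_SEGMENTS = ["anterior", "septal", "inferior", "lateral"]


def make_defect_voi(
    phantom: PhantomTruth, severity: float, seed: int = 0
) -> DefectVOI:
    """Draw a seeded wall-sector defect VOI inside the myocardium.

    The sector spans a random angular window of 40-90 degrees about the LV
    long axis and 30-60 % of the apex-base extent, entirely inside the
    myocardium mask.
    """
    if not (0.0 < severity <= 1.0):
        raise ValueError("severity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    spec = phantom.spec
    mask = phantom.myo_mask.data > 0

    x, y, z = _mm_grids(spec, np.asarray(phantom.centre_mm))
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    zvals = z[mask]
    z_lo, z_hi = zvals.min(), zvals.max()

    for _ in range(64):  # retry until the sector intersects the wall
        centre_deg = rng.uniform(0.0, 360.0)
        extent_deg = rng.uniform(40.0, 90.0)
        z_frac = rng.uniform(0.30, 0.60)
        span = (z_hi - z_lo) * z_frac
        z0 = rng.uniform(z_lo, z_hi - span)
        dang = np.abs((ang - centre_deg + 180.0) % 360.0 - 180.0)
        voi = mask & (dang <= extent_deg / 2.0) & (z >= z0) & (z <= z0 + span)
        if voi.any():
            seg = _SEGMENTS[int(((centre_deg + 45.0) % 360.0) // 90.0)]
            return DefectVOI(
                mask=Volume(voi.astype(np.float64), spec.voxel_mm),
                severity=severity,
                location=seg,
                extent_deg=extent_deg,
                extent_z_fraction=z_frac,
            )
    raise RuntimeError("could not place a defect VOI inside the myocardium")
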