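"""Ordered-subsets expectation maximization (OSEM) with Gaussian post-filter.

Clinical-style settings: 16 subsets, 5 iterations, 1.25 cm FWHM 3D Gaussian
post-filter.  Subsets partition the views by stride (view ``i`` belongs to
subset ``i mod n_subsets``) and are visited in index order; with one subset
the update is plain MLEM, whose Poisson log-likelihood is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import SystemGeometry
from .projector import ProjectionSet, SystemOperator
from .volume import AttenuationMap, Volume

__all__ = ["OsemConfig", "osem", "gaussian_postfilter", "poisson_loglik"]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class OsemConfig:
    """OSEM settings (defaults follow routine cardiac protocols)."""

    n_subsets: int = 16
    n_iterations: int = 5
    postfilter_fwhm_mm: float = 12.5
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.postfilter_fwhm_mm < 0:
            raise ValueError("post-filter FWHM must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def gaussian_postfilter(vol: Volume, fwhm_mm: float) -> Volume:
    """Isotropic 3D Gaussian smoothing, sigma = FWHM / 2.3548.

    Reflective boundaries preserve constants; total counts of interior
    sources are conserved to well under 0.1 %.  ``fwhm_mm == 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / vol.voxel_mm
    return vol.like(gaussian_filter(vol.data, sigma_vox, mode="reflect", truncate=4.0))


def poisson_loglik(proj: ProjectionSet, estimate: np.ndarray) -> float:
    """Poisson log-likelihood (up to the data-only term) of a projection
    estimate ``q``: ``sum(p * log q - q)`` with 0*log0 := 0."""
    p = proj.counts
    q = np.clip(estimate, 1e-30, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(q), 0.0)
    return float((term - q).sum())


def osem(
    proj: ProjectionSet,
    attn: AttenuationMap | None,
    geom: SystemGeometry,
    cfg: OsemConfig = OsemConfig(),
    op: SystemOperator | None = None,
    track_likelihood: bool = False,
) -> Volume:
    """Reconstruct a projection set with multiplicative OSEM updates.

    ``f <- f * A_s^T(p_s / (A_s f + eps)) / A_s^T 1`` per subset, run for
    ``n_iterations`` full passes; uniform initialization inside the body
    support (from the attenuation map when given), the Gaussian post-filter
    applied once after the final pass.  Voxels with zero sensitivity in any
    subset are frozen at zero.

    Parameters
    ----------
    op:
        Optional precomputed :class:`SystemOperator` (reused across calls
        that share geometry and attenuation).
    track_likelihood:
        When true, attach the per-iteration Poisson log-likelihood (before
        post-filtering) to the returned volume as ``vol.loglik``.
    """
    if geom.n_views % cfg.n_subsets != 0:
        raise ValueError("n_views must be divisible by n_subsets")
    if np.any(proj.counts < 0):
        raise ValueError("projection counts must be non-negative")

    n = geom.det_cols
    shape = (n, n, geom.det_rows)
    voxel = attn.mu.voxel_mm if attn is not None else geom.pixel_mm
    if op is None:
        op = SystemOperator(geom, shape, voxel, attn)

    subsets = [
        np.arange(s, geom.n_views, cfg.n_subsets) for s in range(cfg.n_subsets)
    ]
    sens = []
    ones_proj = np.ones((len(subsets[0]), geom.det_rows, geom.det_cols))
    for views in subsets:
        sens.append(op.adjoint(ones_proj, views))

    if attn is not None:
        support = attn.mu.data > 0
        f = np.where(support, 1.0, 0.0)
        if not support.any():
            f = np.ones(shape)
    else:
        f = np.ones(shape)

    loglik: list[float] = []
    for _ in range(cfg.n_iterations):
        for views, s_img in zip(subsets, sens):
            est = op.forward(f, views)
            ratio = proj.counts[views] / (est + cfg.epsilon)
            back = op.adjoint(ratio, views)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(s_img > 0, f * back / s_img, 0.0)
            np.clip(f, 0.0, None, out=f)
        if track_likelihood:
            loglik.append(poisson_loglik(proj, op.forward(f)))

    out = gaussian_postfilter(Volume(f, voxel), cfg.postfilter_fwhm_mm)
    if track_likelihood:
        out.loglik = loglik  # type: ignore[attr-defined]
    return out
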