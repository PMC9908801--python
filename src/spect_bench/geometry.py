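"""Acquisition geometry for a parallel-hole SPECT camera.

A single :class:`SystemGeometry` instance describes the orbit (number of
views over an arc), the detector matrix, and the depth-dependent collimator
response.  The defaults mirror a routine gated myocardial-perfusion
acquisition: 64 projections over a 180 degree rotation on a 128 x 128
matrix with 4.8 mm pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SystemGeometry"]


@dataclass(frozen=True)
class SystemGeometry:
    """Parallel-beam orbit and collimator description.

    Parameters
    ----------
    n_views:
        Number of projection angles.
    arc_deg:
        Total rotation arc in degrees.  The arc is half-open: view ``i`` sits
        at ``i * arc_deg / n_views``, so a 180 degree orbit never duplicates
        the opposite view.
    det_rows, det_cols:
        Detector matrix size.  Rows run along the rotation (z) axis.
    pixel_mm:
        Detector pixel pitch, equal to the reconstruction voxel size.
    radius_mm:
        Detector orbit radius (distance rotation axis -> collimator face).
    psf_sigma0_mm:
        Gaussian collimator blur (sigma) at the collimator face.
    psf_slope:
        Dimensionless growth of sigma per mm of source depth.  Setting both
        PSF parameters to zero disables the distance-dependent blur.
    """

    n_views: int = 64
    arc_deg: float = 180.0
    det_rows: int = 128
    det_cols: int = 128
    pixel_mm: float = 4.8
    radius_mm: float = 320.0
    psf_sigma0_mm: float = 1.5
    psf_slope: float = 0.02

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if not (0.0 < self.arc_deg <= 360.0):
            raise ValueError("arc_deg must lie in (0, 360]")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if self.det_rows < 1 or self.det_cols < 1:
            raise ValueError("detector matrix must be at least 1 x 1")
        if self.psf_sigma0_mm < 0 or self.psf_slope < 0:
            raise ValueError("PSF parameters must be non-negative")

    @property
    def view_angles_deg(self) -> np.ndarray:
        """Angles of all views in degrees (half-open arc)."""
        return np.arange(self.n_views) * (self.arc_deg / self.n_views)

    @property
    def psf_enabled(self) -> bool:
        return self.psf_sigma0_mm > 0 or self.psf_slope > 0

    def with_matrix(self, det_rows: int, det_cols: int) -> "SystemGeometry":
        """Return a copy resized to a different detector matrix."""
        return SystemGeometry(
            n_views=self.n_views,
            arc_deg=self.arc_deg,
            det_rows=det_rows,
            det_cols=det_cols,
            pixel_mm=self.pixel_mm,
            radius_mm=self.radius_mm,
            psf_sigma0_mm=self.psf_sigma0_mm,
            psf_slope=self.psf_slope,
        )
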