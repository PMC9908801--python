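"""Overlapping 3D patch extraction and inverse-distance recombination.

Reconstructions are cropped into ``size^3`` patches on a regular stride
lattice (defaults 32/8, the training-time layout), and denoised patches are
recombined by weighted averaging where each voxel's weight is the inverse of
its Euclidean distance from the patch centre.  Cropping a volume and
recombining it unchanged is the exact identity, since every contribution to
a voxel carries the same value.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .volume import Volume

__all__ = ["PatchSet", "crop_patches", "recombine_patches", "save_patchset", "load_patchset"]

CENTRE_DELTA = 0.5  # voxels added to the distance to avoid the centre singularity


def _lattice(dim: int, size: int, stride: int) -> tuple[int, int]:
    """Number of patches along one axis and the padded dimension."""
    k = max(1, int(np.ceil((dim - size) / stride)) + 1)
    padded = (k - 1) * stride + size
    return k, padded


@dataclass
class PatchSet:
    """Patches plus the bookkeeping needed for lossless recombination."""

    patches: np.ndarray  # [k, s, s, s]
    origins: np.ndarray  # [k, 3] offsets into the padded grid
    source_shape: tuple[int, int, int]
    size: int
    stride: int
    pad_before: tuple[int, int, int]
    voxel_mm: float = 4.8

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.origins = np.asarray(self.origins, dtype=np.int64)
        if self.patches.ndim != 4 or self.patches.shape[1:] != (self.size,) * 3:
            raise ValueError("patches must be a [k, s, s, s] stack")
        if len(self.origins) != len(self.patches):
            raise ValueError("origins and patches disagree in length")

    def __len__(self) -> int:
        return len(self.patches)

    def with_patches(self, patches: np.ndarray) -> "PatchSet":
        """Same lattice, new patch values (e.g. after denoising)."""
        return PatchSet(
            patches, self.origins, self.source_shape, self.size, self.stride,
            self.pad_before, self.voxel_mm,
        )


def centre_weights(size: int, delta: float = CENTRE_DELTA) -> np.ndarray:
    """Inverse-distance weight field ``1 / (d + delta)``, maximal at the
    patch centre ``(size - 1) / 2`` per axis."""
    c = (size - 1) / 2.0
    ax = np.arange(size) - c
    d = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    return 1.0 / (d + delta)


def crop_patches(vol: Volume, size: int = 32, stride: int = 8) -> PatchSet:
    """Crop a volume into an overlapping patch lattice covering every voxel.

    The volume is zero-padded symmetrically so the lattice tiles it exactly;
    origins are enumerated in raster order.  Deterministic.
    """
    if not (1 <= stride <= size):
        raise ValueError("need size >= stride >= 1")
    dims = vol.shape
    ks, padded = zip(*(_lattice(d, size, stride) for d in dims))
    pad_before = tuple((p - d) // 2 for p, d in zip(padded, dims))
    pad_after = tuple(p - d - b for p, d, b in zip(padded, dims, pad_before))
    data = np.pad(vol.data, tuple(zip(pad_before, pad_after)))

    origins = []
    patches = []
    for i in range(ks[0]):
        for jj in range(ks[1]):
            for kk in range(ks[2]):
                o = (i * stride, jj * stride, kk * stride)
                origins.append(o)
                patches.append(data[o[0]:o[0] + size, o[1]:o[1] + size, o[2]:o[2] + size])
    return PatchSet(
        np.stack(patches), np.asarray(origins), dims, size, stride,
        pad_before, vol.voxel_mm,
    )


def recombine_patches(ps: PatchSet) -> Volume:
    """Weighted-average recombination of overlapping patches.

    Each output voxel is ``sum(w_i v_i) / sum(w_i)`` over all patches that
    cover it, with ``w = 1 / (d + 0.5)`` and ``d`` the voxel's distance from
    its patch centre.  Padding margins are discarded.
    """
    if len(ps) == 0:
        raise ValueError("empty patch set")
    s = ps.size
    w = centre_weights(s)
    padded = tuple(
        _lattice(d, s, ps.stride)[1] for d in ps.source_shape
    )
    num = np.zeros(padded)
    den = np.zeros(padded)
    for patch, o in zip(ps.patches, ps.origins):
        sl = tuple(slice(oo, oo + s) for oo in o)
        num[sl] += w * patch
        den[sl] += w
    if np.any(den == 0):
        raise ValueError("patch lattice does not cover the padded grid")
    out = num / den
    b = ps.pad_before
    d0, d1, d2 = ps.source_shape
    return Volume(out[b[0]:b[0] + d0, b[1]:b[1] + d1, b[2]:b[2] + d2], ps.voxel_mm)


def save_patchset(ps: PatchSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=ps.patches.astype(np.float32))
        f.create_dataset("origins", data=ps.origins)
        f.attrs["source_shape"] = ps.source_shape
        f.attrs["size"] = ps.size
        f.attrs["stride"] = ps.stride
        f.attrs["pad_before"] = ps.pad_before
        f.attrs["voxel_mm"] = ps.voxel_mm


def load_patchset(path: str) -> PatchSet:
    with h5py.File(path, "r") as f:
        return PatchSet(
            f["patches"][()].astype(np.float64),
            f["origins"][()],
            tuple(int(v) for v in f.attrs["source_shape"]),
            int(f.attrs["size"]),
            int(f.attrs["stride"]),
            tuple(int(v) for v in f.attrs["pad_before"]),
            float(f.attrs["voxel_mm"]),
        )
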