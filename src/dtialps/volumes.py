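"""In-memory containers for diffusion volumes.

All volumes carry a 4x4 voxel-to-world affine in RAS millimetre
coordinates: +x = left-to-right, +y = posterior-to-anterior,
+z = inferior-to-superior.  Gradient directions (b-vectors) are
interpreted in the same world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

# Order of the unique tensor entries along the component axis.
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

# Index pairs mapping the 6-vector to the symmetric 3x3 matrix.
_COMP_IDX = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


class FormatError(ValueError):
    """Raised when an on-disk volume or sidecar violates the expected layout."""


class InvalidDesignError(ValueError):
    """Raised when a diffusion acquisition cannot support a tensor fit."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class DWIVolume:
    """Diffusion-weighted signal volume with its acquisition scheme.

    Parameters
    ----------
    signal : (X, Y, Z, N) array
        Non-negative signal intensities, one 3-D volume per gradient.
    bvals : (N,) array
        b-values in s/mm^2; at least one must be 0.
    bvecs : (N, 3) array
        Unit gradient directions in world (RAS) coordinates; rows with
        bval == 0 may be the zero vector.
    affine : (4, 4) array
        Voxel-to-world transform (RAS, mm).
    mask : (X, Y, Z) bool array, optional
        Voxels to fit; defaults to the full grid.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.affine = _check_affine(self.affine)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        n = self.signal.shape[3]
        if self.bvals.shape != (n,):
            raise FormatError(
                f"bvals: expected {n} entries to match {n} volumes, got {self.bvals.size}"
            )
        if self.bvecs.shape != (n, 3):
            raise FormatError(
                f"bvecs: expected shape ({n}, 3), got {self.bvecs.shape}"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal intensities must be non-negative")
        if not np.any(self.bvals == 0):
            raise InvalidDesignError("at least one b=0 volume is required")
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-zero b-vectors must have unit norm (tol 1e-6)")
        if _n_independent_directions(self.bvecs[weighted]) < 6:
            raise InvalidDesignError(
                "tensor fitting needs >= 6 non-collinear gradient directions"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signal.shape[:3]:
                raise ValueError("mask shape must match the spatial grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]


def _n_independent_directions(bvecs: np.ndarray) -> int:
    """Rank of the quadratic-form design spanned by the directions.

    Six independent tensor components require the outer-product design
    g -> (gx^2, gy^2, gz^2, gxgy, gxgz, gygz) to have rank 6.
    """
    if len(bvecs) == 0:
        return 0
    g = np.asarray(bvecs, dtype=float)
    design = np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         g[:, 0] * g[:, 1], g[:, 0] * g[:, 2], g[:, 1] * g[:, 2]]
    )
    return int(np.linalg.matrix_rank(design, tol=1e-8))


@dataclass
class TensorVolume:
    """Grid of symmetric diffusion tensors.

    ``components`` stores the six unique entries in the order
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz), units mm^2/s, on a 3-D voxel grid.
    ``flags`` marks voxels where eigenvalue clamping or signal exclusion
    occurred during fitting (0 = clean).
    """

    components: np.ndarray
    affine: np.ndarray
    flags: np.ndarray | None = None

    axis_convention: str = field(
        default="x=left-right, y=anterior-posterior, z=head-foot (world RAS)",
        repr=False,
    )

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.affine = _check_affine(self.affine)
        if self.components.ndim != 4 or self.components.shape[3] != 6:
            raise ValueError(
                "components must be (x, y, z, 6) in (Dxx,Dxy,Dxz,Dyy,Dyz,Dzz) order"
            )
        if self.flags is not None:
            self.flags = np.asarray(self.flags)
            if self.flags.shape != self.components.shape[:3]:
                raise ValueError("flags shape must match the spatial grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand to a (X, Y, Z, 3, 3) array of symmetric matrices."""
        m = np.zeros(self.shape + (3, 3), dtype=float)
        for k, (i, j) in enumerate(_COMP_IDX):
            m[..., i, j] = self.components[..., k]
            m[..., j, i] = self.components[..., k]
        return m

    @classmethod
    def from_matrices(cls, matrices: np.ndarray, affine: np.ndarray,
                      flags: np.ndarray | None = None) -> "TensorVolume":
        matrices = np.asarray(matrices, dtype=float)
        comps = np.stack([matrices[..., i, j] for (i, j) in _COMP_IDX], axis=-1)
        return cls(components=comps, affine=affine, flags=flags)

    def diagonal(self) -> np.ndarray:
        """(X, Y, Z, 3) array of (Dxx, Dyy, Dzz)."""
        return self.components[..., [0, 3, 5]]


@dataclass
class ScalarVolume:
    """Scalar map derived from a tensor volume (FA is dimensionless, MD mm^2/s)."""

    values: np.ndarray
    affine: np.ndarray
    kind: Literal["FA", "MD"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = _check_affine(self.affine)
        if self.values.ndim != 3:
            raise ValueError("scalar map must be 3-D")
        if self.kind == "FA":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("FA values must lie in [0, 1]")
        elif self.kind == "MD":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < -1e-12:
                raise ValueError("MD must be non-negative")
        else:
            raise ValueError(f"unknown scalar kind {self.kind!r}")
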