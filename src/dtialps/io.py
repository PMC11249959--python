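"""NIfTI input/output for diffusion volumes.

Tensors are stored as 4-D NIfTI with six components in the order
(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz); b-values and b-vectors live in
whitespace-separated text sidecars (FSL-style: one row of b-values;
b-vectors as either three rows or three columns).

Volumes whose affine is not RAS-oriented are reoriented on load so that
voxel axes align with x=left-right, y=anterior-posterior, z=head-foot.
Tensor components are rotated accordingly.  B-vectors are interpreted in
world (RAS) coordinates and therefore unchanged by reorientation.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .volumes import DWIVolume, FormatError, ScalarVolume, TensorVolume


def _ras_reorient(data: np.ndarray, affine: np.ndarray):
    """Reorient voxel data to closest-to-RAS axes; return (data, affine, R).

    R is the 3x3 signed permutation taking old voxel axes to new ones;
    callers rotating per-voxel tensors need it.
    """
    ornt = nib.orientations.io_orientation(affine)
    if np.array_equal(ornt, [[0, 1], [1, 1], [2, 1]]):
        return data, affine, np.eye(3)
    data = nib.orientations.apply_orientation(data, ornt)
    new_affine = affine @ nib.orientations.inv_ornt_aff(ornt, data.shape[:3])
    # signed permutation: new axis k comes from old axis ornt[k,0] with flip ornt[k,1]
    R = np.zeros((3, 3))
    for new_ax in range(3):
        old_ax = int(ornt[new_ax, 0])
        R[new_ax, old_ax] = ornt[new_ax, 1]
    return data, new_affine, R


def write_tensor(t: TensorVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(t.components.astype(np.float64), t.affine)
    img.header.set_intent("symmetric matrix")
    nib.save(img, os.fspath(path))


def read_tensor(path: str | os.PathLike) -> TensorVolume:
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 6:
        raise FormatError(
            f"{path}: tensor volume must be 4-D with 6 components, got shape {data.shape}"
        )
    data, affine, R = _ras_reorient(data, np.asarray(img.affine))
    if not np.allclose(R, np.eye(3)):
        # rotate tensors into the new voxel frame: D' = R D R^T
        t = TensorVolume(components=data, affine=affine)
        m = np.einsum("ai,...ij,bj->...ab", R, t.as_matrices(), R)
        return TensorVolume.from_matrices(m, affine)
    return TensorVolume(components=data, affine=affine)


def write_scalar(s: ScalarVolume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(s.values.astype(np.float64), s.affine), os.fspath(path))


def read_scalar(path: str | os.PathLike, kind: str) -> ScalarVolume:
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: scalar map must be 3-D, got shape {data.shape}")
    data, affine, _ = _ras_reorient(data, np.asarray(img.affine))
    return ScalarVolume(values=data, affine=affine, kind=kind)


def write_dwi(dwi: DWIVolume, nifti_path, bval_path, bvec_path) -> None:
    nib.save(nib.Nifti1Image(dwi.signal.astype(np.float64), dwi.affine),
             os.fspath(nifti_path))
    np.savetxt(os.fspath(bval_path), dwi.bvals[None, :], fmt="%.6g")
    # FSL convention: three rows of components
    np.savetxt(os.fspath(bvec_path), dwi.bvecs.T, fmt="%.10g")


def read_bvals(path: str | os.PathLike, n_volumes: int | None = None) -> np.ndarray:
    vals = np.loadtxt(os.fspath(path)).ravel()
    if n_volumes is not None and vals.size != n_volumes:
        raise FormatError(
            f"{path}: bvals has {vals.size} entries but the volume has "
            f"{n_volumes} diffusion volumes"
        )
    return vals


def read_bvecs(path: str | os.PathLike, n_volumes: int | None = None) -> np.ndarray:
    """Parse b-vectors, accepting both 3xN (row) and Nx3 (column) layouts."""
    arr = np.atleast_2d(np.loadtxt(os.fspath(path)))
    if arr.shape[0] == 3 and (arr.shape[1] != 3 or n_volumes == arr.shape[1]):
        arr = arr.T
    elif arr.shape[1] != 3:
        if arr.shape[0] == 3:
            arr = arr.T
        else:
            raise FormatError(f"{path}: b-vectors must be 3xN or Nx3, got {arr.shape}")
    if n_volumes is not None and arr.shape[0] != n_volumes:
        raise FormatError(
            f"{path}: bvecs has {arr.shape[0]} directions but the volume has "
            f"{n_volumes} diffusion volumes"
        )
    return arr


def read_dwi(nifti_path, bval_path, bvec_path,
             mask: np.ndarray | None = None) -> DWIVolume:
    img = nib.load(os.fspath(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: DWI must be 4-D, got shape {data.shape}")
    data, affine, _ = _ras_reorient(data, np.asarray(img.affine))
    n = data.shape[3]
    bvals = read_bvals(bval_path, n)
    bvecs = read_bvecs(bvec_path, n)
    return DWIVolume(signal=data, bvals=bvals, bvecs=bvecs, affine=affine, mask=mask)
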