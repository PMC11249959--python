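"""Diffusion tensor estimation and scalar maps.

The tensor is fit per voxel from the log-linearised signal equation

    ln S_i = ln S0 - b_i g_i^T D g_i

by a two-stage procedure: an ordinary least-squares pass on ln S,
followed by one weighted pass with weights equal to the squared
predicted signals (the standard WLS correction for the log transform).
Negative eigenvalues after the fit are clamped to zero and the voxel
flagged; signals <= 0 are excluded per voxel, and a voxel with fewer
than 7 usable volumes is marked unfittable.
"""

from __future__ import annotations

import numpy as np

from .volumes import DWIVolume, InvalidDesignError, ScalarVolume, TensorVolume

# flag bit values recorded per voxel during fitting
FLAG_CLAMPED = 1      # negative eigenvalue clamped to zero
FLAG_EXCLUDED = 2     # some non-positive signals dropped for this voxel
FLAG_UNFITTABLE = 4   # fewer than 7 usable volumes; tensor left zero


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """(N, 7) design for theta = (ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -b * g[:, 1] ** 2,
        -2 * b * g[:, 1] * g[:, 2],
        -b * g[:, 2] ** 2,
    ])


def _clamp_psd(comps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project 6-component tensors onto the PSD cone.

    Returns the projected components and a boolean array marking voxels
    whose eigenvalues were clamped.
    """
    flat = comps.reshape(-1, 6)
    m = np.zeros((flat.shape[0], 3, 3))
    m[:, 0, 0] = flat[:, 0]
    m[:, 0, 1] = m[:, 1, 0] = flat[:, 1]
    m[:, 0, 2] = m[:, 2, 0] = flat[:, 2]
    m[:, 1, 1] = flat[:, 3]
    m[:, 1, 2] = m[:, 2, 1] = flat[:, 4]
    m[:, 2, 2] = flat[:, 5]
    w, v = np.linalg.eigh(m)
    clamped = (w < 0).any(axis=1)
    if clamped.any():
        w_clamped = np.clip(w[clamped], 0.0, None)
        m_new = np.einsum("nij,nj,nkj->nik", v[clamped], w_clamped, v[clamped])
        out = flat.copy()
        out[clamped] = np.stack(
            [m_new[:, 0, 0], m_new[:, 0, 1], m_new[:, 0, 2],
             m_new[:, 1, 1], m_new[:, 1, 2], m_new[:, 2, 2]], axis=1)
        return out.reshape(comps.shape), clamped.reshape(comps.shape[:-1])
    return comps, clamped.reshape(comps.shape[:-1])


def _fit_block(signal: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-stage log-linear fit for voxels sharing the full design.

    signal: (V, N) strictly positive; X: (N, 7).  Returns (V, 7) theta.
    """
    y = np.log(signal)
    theta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # (V, 7) OLS pass
    # WLS pass: weights are squared predicted signals
    pred = theta @ X.T
    w = np.exp(2.0 * np.clip(pred, -700, 700))
    Xw = w[:, :, None] * X[None, :, :]           # (V, N, 7)
    A = np.einsum("ni,vnj->vij", X, Xw)          # (V, 7, 7)
    rhs = np.einsum("vn,vn,ni->vi", w, y, X)     # (V, 7)
    try:
        return np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.stack([np.linalg.lstsq(A[i], rhs[i], rcond=None)[0]
                         for i in range(A.shape[0])])


def fit_tensor(dwi: DWIVolume) -> TensorVolume:
    """Fit a diffusion tensor at every in-mask voxel.

    Voxels outside the mask are zero tensors.  Per voxel, non-positive
    signals are dropped before fitting; if fewer than 7 usable volumes
    remain the voxel is flagged unfittable and left zero.
    """
    X = design_matrix(dwi.bvals, dwi.bvecs)
    if np.linalg.matrix_rank(X, tol=1e-10) < 7:
        raise InvalidDesignError("gradient scheme does not span the tensor space")

    shape = dwi.shape
    mask = dwi.mask if dwi.mask is not None else np.ones(shape, dtype=bool)
    comps = np.zeros(shape + (6,), dtype=float)
    flags = np.zeros(shape, dtype=np.uint8)

    sig = dwi.signal[mask]                       # (V, N)
    idx = np.argwhere(mask)
    pos = sig > 0
    all_pos = pos.all(axis=1)

    if all_pos.any():
        theta = _fit_block(sig[all_pos], X)
        comps[tuple(idx[all_pos].T)] = theta[:, 1:]

    # voxels with some non-positive signals: fit each on its usable subset
    for row in np.argwhere(~all_pos).ravel():
        usable = pos[row]
        if usable.sum() < 7 or _usable_design_ok(X[usable]) is False:
            flags[tuple(idx[row])] |= FLAG_UNFITTABLE
            continue
        theta = _fit_block(sig[row][usable][None, :], X[usable])
        comps[tuple(idx[row])] = theta[0, 1:]
        flags[tuple(idx[row])] |= FLAG_EXCLUDED

    comps, clamped = _clamp_psd(comps)
    flags[clamped] |= FLAG_CLAMPED
    # unfittable voxels drop out of the effective mask
    fitted_mask = mask & (flags & FLAG_UNFITTABLE == 0)
    comps[~fitted_mask] = 0.0
    return TensorVolume(components=comps, affine=dwi.affine, flags=flags)


def _usable_design_ok(Xsub: np.ndarray) -> bool:
    return np.linalg.matrix_rank(Xsub, tol=1e-10) >= 7


def tensor_eigenvalues(t: TensorVolume) -> np.ndarray:
    """(X, Y, Z, 3) eigenvalues in ascending order."""
    return np.linalg.eigvalsh(t.as_matrices())


def fa_map(t: TensorVolume) -> ScalarVolume:
    """Fractional anisotropy: sqrt(3/2) * ||lambda - mean|| / ||lambda||.

    Zero tensors map to FA = 0.
    """
    lam = tensor_eigenvalues(t)
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return ScalarVolume(values=np.clip(fa, 0.0, 1.0), affine=t.affine, kind="FA")


def md_map(t: TensorVolume) -> ScalarVolume:
    """Mean diffusivity: trace(D) / 3 per voxel."""
    md = t.diagonal().sum(axis=-1) / 3.0
    return ScalarVolume(values=np.clip(md, 0.0, None), affine=t.affine, kind="MD")


def principal_eigenvectors(t: TensorVolume) -> np.ndarray:
    """(X, Y, Z, 3) unit eigenvector of the largest eigenvalue per voxel."""
    _, v = np.linalg.eigh(t.as_matrices())
    return v[..., :, 2]
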