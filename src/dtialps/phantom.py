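"""Digital periventricular tensor phantoms and simulated DWI signals.

The phantom emulates the geometry the ALPS index relies on: per
hemisphere, a block of projection fibres (dominant diffusion head-foot,
z) medially and a block of association fibres (dominant diffusion
anterior-posterior, y) laterally, embedded in isotropic background.  A
perivascular diffusivity increment ``epsilon`` is added to Dxx inside
both fibre blocks, so the ground-truth ALPS index has the closed form

    (lambda_perp + epsilon) / lambda_perp

in both hemispheres under symmetric parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rois import ROISet, SphereROI
from .tensor import fa_map
from .volumes import DWIVolume, ScalarVolume, TensorVolume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tensor parameters of the periventricular phantom.

    Diffusivities in mm^2/s.  Defaults give healthy-white-matter-like
    fibres (lambda_par 1.4e-3, lambda_perp 0.4e-3) and a perivascular
    increment placing the ground-truth index at 1.3.
    """

    shape: tuple[int, int, int] = (64, 48, 48)
    voxel_size: float = 1.0
    lambda_par: float = 1.4e-3
    lambda_perp: float = 0.4e-3
    epsilon: float = 0.12e-3
    background_d: float = 0.8e-3
    tensor_noise_sd: float = 0.0
    seed: int = 0
    # region geometry (world mm, per hemisphere): |x| spans, y/z half-width
    projection_x: tuple[float, float] = (3.0, 15.0)
    association_x: tuple[float, float] = (16.0, 28.0)
    region_halfwidth: float = 10.0
    roi_radius: float = 5.0

    def __post_init__(self) -> None:
        if not (self.lambda_par > self.lambda_perp > 0):
            raise ValueError("need lambda_par > lambda_perp > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.tensor_noise_sd < 0:
            raise ValueError("tensor_noise_sd must be >= 0")
        for lo, hi, name in (
            (*self.projection_x, "projection_x"),
            (*self.association_x, "association_x"),
        ):
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < lo < hi")
            if hi - lo < 2 * self.roi_radius:
                raise ValueError(
                    f"{name} span {hi - lo:g} mm cannot contain a radius-"
                    f"{self.roi_radius:g} sphere"
                )
        if self.projection_x[1] > self.association_x[0]:
            raise ValueError("projection and association regions overlap")
        if self.region_halfwidth < self.roi_radius:
            raise ValueError("region halfwidth smaller than ROI radius")

    @property
    def ground_truth_index(self) -> float:
        return (self.lambda_perp + self.epsilon) / self.lambda_perp


def _centered_affine(shape, voxel_size: float) -> np.ndarray:
    """RAS affine placing the grid center at the world origin."""
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size
    return aff


def make_phantom(spec: PhantomSpec):
    """Build the phantom.

    Returns ``(tensor, fa, ground_truth, rois)`` where ``ground_truth``
    is a dict with the closed-form left/right/mean index and ``rois`` is
    the matching ROISet centered in each fibre block.
    """
    rng = np.random.default_rng(spec.seed)
    affine = _centered_affine(spec.shape, spec.voxel_size)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in spec.shape), indexing="ij")
    world = (np.stack([ii, jj, kk], axis=-1) @ affine[:3, :3].T) + affine[:3, 3]
    x, y, z = world[..., 0], world[..., 1], world[..., 2]

    comps = np.zeros(spec.shape + (6,), dtype=float)
    iso = spec.background_d
    comps[..., 0] = iso
    comps[..., 3] = iso
    comps[..., 5] = iso

    in_slab = (np.abs(y) <= spec.region_halfwidth) & (np.abs(z) <= spec.region_halfwidth)
    proj = in_slab & (np.abs(x) >= spec.projection_x[0]) & (np.abs(x) <= spec.projection_x[1])
    assoc = in_slab & (np.abs(x) >= spec.association_x[0]) & (np.abs(x) <= spec.association_x[1])

    # projection fibres: dominant z; association fibres: dominant y;
    # both carry the perivascular increment on Dxx
    comps[proj] = [spec.lambda_perp + spec.epsilon, 0, 0, spec.lambda_perp, 0, spec.lambda_par]
    comps[assoc] = [spec.lambda_perp + spec.epsilon, 0, 0, spec.lambda_par, 0, spec.lambda_perp]

    if spec.tensor_noise_sd > 0:
        comps[..., [0, 3, 5]] += rng.normal(0.0, spec.tensor_noise_sd, spec.shape + (3,))
        from .tensor import _clamp_psd
        comps, _ = _clamp_psd(comps)

    tensor = TensorVolume(components=comps, affine=affine)
    fa = fa_map(tensor)

    proj_cx = (spec.projection_x[0] + spec.projection_x[1]) / 2.0
    assoc_cx = (spec.association_x[0] + spec.association_x[1]) / 2.0
    rois = ROISet(tuple(
        SphereROI(label=f"{kind}_{hemi}", center=(sign * cx, 0.0, 0.0),
                  radius=spec.roi_radius)
        for kind, cx in (("projection", proj_cx), ("association", assoc_cx))
        for hemi, sign in (("left", -1.0), ("right", 1.0))
    ))
    gt = spec.ground_truth_index
    ground_truth = {"alps_left": gt, "alps_right": gt, "alps_mean": gt}
    return tensor, fa, ground_truth, rois


def default_protocol(n_b0: int = 5, n_dirs: int = 61, bval: float = 1000.0):
    """GENFI-like single-shell scheme: b0 volumes plus a deterministic
    quasi-uniform spread of unit directions (Fibonacci sphere)."""
    i = np.arange(n_dirs)
    golden = (1 + 5 ** 0.5) / 2
    zc = 1 - 2 * (i + 0.5) / n_dirs
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - zc ** 2)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), zc])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, bval)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def simulate_dwi(t: TensorVolume, bvals, bvecs, s0: float = 1000.0,
                 noise_sd: float = 0.0, seed: int = 0,
                 noise_model: str = "rician") -> DWIVolume:
    """Forward-simulate single-shell DWI: S = S0 exp(-b g^T D g).

    Rician noise adds independent Gaussian channels in quadrature
    (magnitude reconstruction); Gaussian noise adds directly, clipped
    at zero to keep signals valid.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    m = t.as_matrices()
    quad = np.einsum("ni,...ij,nj->...n", bvecs, m, bvecs)  # g^T D g per volume
    signal = s0 * np.exp(-bvals * quad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            re = signal + rng.normal(0, noise_sd, signal.shape)
            im = rng.normal(0, noise_sd, signal.shape)
            signal = np.hypot(re, im)
        elif noise_model == "gaussian":
            signal = np.clip(signal + rng.normal(0, noise_sd, signal.shape), 0, None)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return DWIVolume(signal=signal, bvals=bvals, bvecs=bvecs, affine=t.affine)
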