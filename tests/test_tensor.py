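"""Tensor model: fitting, FA and MD."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dtialps import DWIVolume, TensorVolume, fa_map, fit_tensor, md_map, simulate_dwi
from dtialps.tensor import FLAG_EXCLUDED, FLAG_UNFITTABLE, tensor_eigenvalues
from dtialps.volumes import InvalidDesignError


def _single_voxel_dwi(D, bvals, bvecs, s0=1000.0):
    t = TensorVolume.from_matrices(np.asarray(D)[None, None, None], np.eye(4))
    return simulate_dwi(t, bvals, bvecs, s0=s0)


def _scheme(fib_dirs, n_b0, n_dirs, bval=1000.0):
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, bval)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fib_dirs(n_dirs)])
    return bvals, bvecs


class TestFitTensor:
    def test_noise_free_recovery_single_voxel(self, fib_dirs):
        """Forward-simulated signals from a known tensor refit exactly."""
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        bvals, bvecs = _scheme(fib_dirs, 1, 21)
        dwi = _single_voxel_dwi(D, bvals, bvecs)
        fit = fit_tensor(dwi)
        rel = np.abs(fit.as_matrices()[0, 0, 0] - D).max() / D.max()
        assert rel <= 1e-9

    def test_direction_independent_decay_gives_isotropy(self, fib_dirs):
        """Equal attenuation in every direction forces diag(d, d, d)."""
        d = 0.9e-3
        bvals, bvecs = _scheme(fib_dirs, 2, 15)
        signal = 1000.0 * np.exp(-bvals * d) * np.ones((1, 1, 1, len(bvals)))
        dwi = DWIVolume(signal=signal, bvals=bvals, bvecs=bvecs, affine=np.eye(4))
        fit = fit_tensor(dwi)
        assert np.allclose(fit.as_matrices()[0, 0, 0], np.eye(3) * d, atol=1e-12)

    @pytest.mark.parametrize("n_b0,n_dirs", [(4, 61), (5, 61), (4, 64), (5, 64)])
    def test_acquisition_dialects_accepted(self, fib_dirs, n_b0, n_dirs):
        """Both site protocols (4-5 b0, 61 or 64 weighted volumes) fit fine."""
        D = np.diag([1.2e-3, 0.5e-3, 0.4e-3])
        bvals, bvecs = _scheme(fib_dirs, n_b0, n_dirs)
        fit = fit_tensor(_single_voxel_dwi(D, bvals, bvecs))
        assert np.allclose(fit.as_matrices()[0, 0, 0], D, rtol=1e-8)

    def test_round_trip_random_psd_grid(self, fib_dirs):
        """Noise-free simulate -> fit reproduces PSD tensors to <= 1e-8."""
        rng = np.random.default_rng(11)
        shape = (5, 4, 3)
        q, _ = np.linalg.qr(rng.normal(size=(np.prod(shape), 3, 3)))
        lam = rng.uniform(0.1e-3, 3e-3, (np.prod(shape), 3))
        m = np.einsum("nij,nj,nkj->nik", q, lam, q).reshape(shape + (3, 3))
        t = TensorVolume.from_matrices(m, np.eye(4))
        bvals, bvecs = _scheme(fib_dirs, 5, 61)
        fit = fit_tensor(simulate_dwi(t, bvals, bvecs))
        rel = np.abs(fit.components - t.components).max() / np.abs(t.components).max()
        assert rel <= 1e-8

    def test_volume_order_permutation_invariance(self, fib_dirs):
        D = np.diag([1.5e-3, 0.6e-3, 0.3e-3])
        bvals, bvecs = _scheme(fib_dirs, 3, 30)
        dwi = _single_voxel_dwi(D, bvals, bvecs)
        perm = np.random.default_rng(5).permutation(len(bvals))
        dwi_p = DWIVolume(signal=dwi.signal[..., perm], bvals=bvals[perm],
                          bvecs=bvecs[perm], affine=np.eye(4))
        f1 = fit_tensor(dwi).components
        f2 = fit_tensor(dwi_p).components
        assert np.allclose(f1, f2, rtol=1e-10)

    def test_too_few_directions_rejected(self):
        bvals = np.array([0.0] + [1000.0] * 5)
        dirs = np.eye(3)
        bvecs = np.vstack([np.zeros(3), dirs, dirs[:2]])
        with pytest.raises(InvalidDesignError):
            DWIVolume(signal=np.ones((1, 1, 1, 6)), bvals=bvals, bvecs=bvecs,
                      affine=np.eye(4))

    def test_nonpositive_signals_excluded_per_voxel(self, fib_dirs):
        D = np.diag([1.0e-3, 0.8e-3, 0.6e-3])
        bvals, bvecs = _scheme(fib_dirs, 2, 20)
        dwi = _single_voxel_dwi(D, bvals, bvecs)
        sig = np.repeat(dwi.signal, 2, axis=0)  # two voxels
        sig[1, 0, 0, 5] = 0.0                   # one dead measurement
        fit = fit_tensor(DWIVolume(signal=sig, bvals=bvals, bvecs=bvecs,
                                   affine=np.eye(4)))
        assert fit.flags[1, 0, 0] & FLAG_EXCLUDED
        assert np.allclose(fit.as_matrices()[1, 0, 0], D, rtol=1e-8)

    def test_voxel_with_too_few_usable_volumes_unfittable(self, fib_dirs):
        bvals, bvecs = _scheme(fib_dirs, 2, 20)
        sig = np.ones((1, 1, 1, 22)) * 500.0
        sig[0, 0, 0, 6:] = 0.0                  # only 6 usable volumes remain
        fit = fit_tensor(DWIVolume(signal=sig, bvals=bvals, bvecs=bvecs,
                                   affine=np.eye(4)))
        assert fit.flags[0, 0, 0] & FLAG_UNFITTABLE
        assert np.all(fit.components[0, 0, 0] == 0.0)

    def test_negative_eigenvalue_clamped_and_flagged(self):
        comps = np.zeros((1, 1, 1, 6))
        comps[0, 0, 0] = [1e-3, 0, 0, -2e-4, 0, 5e-4]
        from dtialps.tensor import _clamp_psd
        out, clamped = _clamp_psd(comps)
        assert clamped[0, 0, 0]
        assert tensor_eigenvalues(TensorVolume(out, np.eye(4))).min() >= -1e-18


class TestScalarMaps:
    def _vol(self, eigvals, rot=None):
        lam = np.asarray(eigvals, dtype=float)
        m = np.diag(lam)
        if rot is not None:
            m = rot @ m @ rot.T
        return TensorVolume.from_matrices(m[None, None, None], np.eye(4))

    @pytest.mark.parametrize("eigvals,expected", [
        ((1e-3, 1e-3, 1e-3), 0.0),                      # isotropy
        ((1e-3, 0.0, 0.0), 1.0),                        # stick limit
        ((1.5e-3, 0.4e-3, 0.4e-3), 0.686161147706986),  # sqrt(121/257)
    ])
    def test_fa_known_values(self, eigvals, expected):
        fa = fa_map(self._vol(eigvals))
        assert fa.values[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_fa_zero_tensor_defined_as_zero(self):
        fa = fa_map(TensorVolume(np.zeros((2, 2, 2, 6)), np.eye(4)))
        assert np.all(fa.values == 0.0)

    @given(st.integers(0, 2 ** 32 - 1), st.floats(0.1, 10.0))
    def test_fa_invariant_to_rotation_and_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(0.1e-3, 3e-3, 3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        fa_plain = fa_map(self._vol(lam)).values[0, 0, 0]
        fa_rot = fa_map(self._vol(lam * scale, rot=q)).values[0, 0, 0]
        assert fa_rot == pytest.approx(fa_plain, abs=1e-9)

    @pytest.mark.parametrize("eigvals,expected", [
        ((1.5e-3, 0.4e-3, 0.4e-3), 0.76666666666667e-3),
        ((0.0, 0.0, 0.0), 0.0),
    ])
    def test_md_known_values(self, eigvals, expected):
        md = md_map(self._vol(eigvals))
        assert md.values[0, 0, 0] == pytest.approx(expected, abs=1e-15)

    def test_md_equals_mean_eigenvalue_and_is_linear(self):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        lam1, lam2 = rng.uniform(0.1e-3, 3e-3, (2, 3))
        m1 = q @ np.diag(lam1) @ q.T
        m2 = q[::-1] @ np.diag(lam2) @ q[::-1].T
        md1 = md_map(TensorVolume.from_matrices(m1[None, None, None], np.eye(4))).values[0, 0, 0]
        assert md1 == pytest.approx(np.linalg.eigvalsh(m1).mean(), rel=1e-12)
        a, b = 0.3, 1.7
        md_sum = md_map(TensorVolume.from_matrices(
            (a * m1 + b * m2)[None, None, None], np.eye(4))).values[0, 0, 0]
        md2 = md_map(TensorVolume.from_matrices(m2[None, None, None], np.eye(4))).values[0, 0, 0]
        assert md_sum == pytest.approx(a * md1 + b * md2, rel=1e-12)
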