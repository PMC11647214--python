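"""Tensor model fits, scalar invariants and free-water recovery."""

import numpy as np
import pytest

from perilesion.datasets import DiffusionDataset, make_affine
from perilesion.phantom import (BundleDef, PhantomSpec, default_spec,
                                generate_phantom, _gradient_table,
                                DEFAULT_SHELL_SCHEME)
from perilesion.tensor import (D_WATER, fit_dti, fit_free_water,
                               scalars_from_eigenvalues)


def _signal_from_tensor(D, bvals, bvecs, f=0.0, s0=1000.0):
    """Independent forward model for oracle signals."""
    q = np.einsum("ab,na,nb->n", D, bvecs, bvecs)
    return s0 * (f * np.exp(-bvals * D_WATER) + (1 - f) * np.exp(-bvals * q))


def _dataset_from_voxel_signal(sig, bvals, bvecs, shape=(1, 1, 1)):
    grid = np.broadcast_to(sig, shape + (len(bvals),)).copy()
    return DiffusionDataset(grid, bvals, bvecs, make_affine(2.0))


@pytest.fixture(scope="module")
def gtab():
    return _gradient_table(DEFAULT_SHELL_SCHEME)


class TestScalars:
    def test_isotropic_eigenvalues(self):
        fa, md, mo = scalars_from_eigenvalues(1e-3, 1e-3, 1e-3)
        assert fa == pytest.approx(0.0)
        assert md == pytest.approx(1e-3)
        assert mo == pytest.approx(0.0)

    def test_prolate_mode_is_plus_one(self):
        _, _, mo = scalars_from_eigenvalues(2.0e-3, 0.5e-3, 0.5e-3)
        assert mo == pytest.approx(1.0, abs=1e-12)

    def test_oblate_mode_is_minus_one(self):
        _, _, mo = scalars_from_eigenvalues(1.0e-3, 1.0e-3, 0.2e-3)
        assert mo == pytest.approx(-1.0, abs=1e-12)

    def test_all_zero_returns_zeros(self):
        assert scalars_from_eigenvalues(0.0, 0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_unsorted_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            scalars_from_eigenvalues(0.3e-3, 1.5e-3, 0.3e-3)

    def test_fa_matches_explicit_formula(self):
        lam = np.array([1.7e-3, 0.4e-3, 0.2e-3])
        fa, md, _ = scalars_from_eigenvalues(*lam)
        expected = np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / np.linalg.norm(lam)
        assert fa == pytest.approx(expected, rel=1e-12)


class TestSingleTensorFit:
    def test_recovers_diagonal_tensor_within_1e6(self, gtab):
        bvals, bvecs = gtab
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        sig = _signal_from_tensor(D, bvals, bvecs)
        fit = fit_dti(_dataset_from_voxel_signal(sig, bvals, bvecs))
        np.testing.assert_allclose(fit.eigenvalues[0, 0, 0],
                                   [1.5e-3, 0.3e-3, 0.3e-3], atol=1e-6)
        assert abs(fit.v1[0, 0, 0] @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-6)

    def test_isotropic_signal_gives_equal_eigenvalues(self, gtab):
        bvals, bvecs = gtab
        sig = _signal_from_tensor(np.eye(3) * 0.8e-3, bvals, bvecs)
        fit = fit_dti(_dataset_from_voxel_signal(sig, bvals, bvecs))
        lam = fit.eigenvalues[0, 0, 0]
        assert np.ptp(lam) < 1e-6 * 1e-3 + 1e-9

    def test_masked_out_voxel_is_invalid(self, gtab):
        bvals, bvecs = gtab
        sig = _signal_from_tensor(np.eye(3) * 1e-3, bvals, bvecs)
        grid = np.broadcast_to(sig, (2, 1, 1, len(bvals))).copy()
        mask = np.array([[[True]], [[False]]])
        fit = fit_dti(DiffusionDataset(grid, bvals, bvecs, make_affine(2.0),
                                       brain_mask=mask))
        assert fit.valid[0, 0, 0] and not fit.valid[1, 0, 0]
        assert np.isnan(fit.eigenvalues[1, 0, 0]).all()

    def test_all_zero_voxel_flagged_not_fatal(self, gtab):
        bvals, bvecs = gtab
        sig = _signal_from_tensor(np.eye(3) * 1e-3, bvals, bvecs)
        grid = np.stack([sig, np.zeros_like(sig)])[:, None, None, :]
        fit = fit_dti(DiffusionDataset(grid, bvals, bvecs, make_affine(2.0)))
        assert fit.valid[0, 0, 0] and not fit.valid[1, 0, 0]

    def test_too_few_volumes_rejected(self):
        bvals = np.array([0, 1000, 1000, 1000])
        bvecs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        sig = np.ones((1, 1, 1, 4)) * 100
        with pytest.raises(ValueError, match="7 volumes"):
            fit_dti(DiffusionDataset(sig, bvals, bvecs, make_affine(2.0)))


class TestFreeWaterFit:
    def test_noiseless_bitensor_recovery(self, gtab):
        """f=0.3, lam=(1.5,0.3,0.3)e-3: f and FA_T within 1e-3 (reg=0)."""
        bvals, bvecs = gtab
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        sig = _signal_from_tensor(D, bvals, bvecs, f=0.3)
        maps = fit_free_water(_dataset_from_voxel_signal(sig, bvals, bvecs))
        fa_true = scalars_from_eigenvalues(1.5e-3, 0.3e-3, 0.3e-3)[0]
        assert maps.fw[0, 0, 0] == pytest.approx(0.3, abs=1e-3)
        assert maps.fa_t[0, 0, 0] == pytest.approx(fa_true, abs=1e-3)
        assert maps.converged[0, 0, 0]

    def test_zero_free_water_matches_uncorrected_fit(self, gtab):
        bvals, bvecs = gtab
        D = np.diag([1.2e-3, 0.4e-3, 0.3e-3])
        sig = _signal_from_tensor(D, bvals, bvecs, f=0.0)
        maps = fit_free_water(_dataset_from_voxel_signal(sig, bvals, bvecs))
        assert maps.fw[0, 0, 0] == pytest.approx(0.0, abs=1e-3)
        assert maps.fa_t[0, 0, 0] == pytest.approx(maps.fa[0, 0, 0], abs=1e-3)

    def test_pure_water_voxel_flagged_unidentifiable(self, gtab):
        bvals, bvecs = gtab
        sig = 1000.0 * np.exp(-bvals * D_WATER)
        maps = fit_free_water(_dataset_from_voxel_signal(sig, bvals, bvecs))
        assert maps.fw[0, 0, 0] == pytest.approx(1.0, abs=0.01)
        assert not maps.identifiable[0, 0, 0]

    def test_single_shell_rejected_as_ill_posed(self):
        bvals = np.concatenate([[0, 0], np.full(30, 1000.0)])
        rng = np.random.default_rng(0)
        v = rng.standard_normal((30, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        bvecs = np.vstack([np.zeros((2, 3)), v])
        sig = _signal_from_tensor(np.eye(3) * 1e-3, bvals, bvecs, f=0.2)
        with pytest.raises(ValueError, match="ill-posed"):
            fit_free_water(_dataset_from_voxel_signal(sig, bvals, bvecs))

    def test_correction_removes_free_water_bias(self, gtab):
        """Raising true f lowers single-tensor FA; FA_T stays at truth."""
        bvals, bvecs = gtab
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        fa_true = scalars_from_eigenvalues(1.5e-3, 0.3e-3, 0.3e-3)[0]
        fa_uncorr, fa_corr = [], []
        for f in (0.0, 0.2, 0.4):
            sig = _signal_from_tensor(D, bvals, bvecs, f=f)
            maps = fit_free_water(_dataset_from_voxel_signal(sig, bvals, bvecs))
            fa_uncorr.append(maps.fa[0, 0, 0])
            fa_corr.append(maps.fa_t[0, 0, 0])
        assert fa_uncorr[0] > fa_uncorr[1] > fa_uncorr[2]
        np.testing.assert_allclose(fa_corr, fa_true, atol=1e-3)

    def test_parameter_recovery_grid_at_snr30(self, gtab):
        """Median |f_hat - f| and |FA_T - FA| below 0.05 at SNR ~= 30."""
        bvals, bvecs = gtab
        rng = np.random.default_rng(42)
        errs_f, errs_fa = [], []
        for f in (0.1, 0.4, 0.7):
            for fa_target, lam in ((0.3, (0.95e-3, 0.65e-3, 0.6e-3)),
                                   (0.8, (1.7e-3, 0.25e-3, 0.25e-3))):
                D = np.diag(lam)
                fa_true = scalars_from_eigenvalues(*lam)[0]
                clean = _signal_from_tensor(D, bvals, bvecs, f=f)
                n_rep = 8
                sig = np.sqrt(
                    (clean + rng.normal(0, 1000 / 30, (n_rep, len(bvals)))) ** 2
                    + rng.normal(0, 1000 / 30, (n_rep, len(bvals))) ** 2)
                data = DiffusionDataset(sig[:, None, None, :], bvals, bvecs,
                                        make_affine(2.0))
                maps = fit_free_water(data)
                errs_f.extend(np.abs(maps.fw[:, 0, 0] - f))
                errs_fa.extend(np.abs(maps.fa_t[:, 0, 0] - fa_true))
        assert np.median(errs_f) < 0.05
        assert np.median(errs_fa) < 0.05

    def test_regularized_fit_runs_and_stays_close_to_voxelwise(self, gtab):
        bvals, bvecs = gtab
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        sig = _signal_from_tensor(D, bvals, bvecs, f=0.3)
        data = DiffusionDataset(
            np.broadcast_to(sig, (3, 3, 3, len(bvals))).copy(),
            bvals, bvecs, make_affine(2.0))
        maps = fit_free_water(data, reg_weight=0.1)
        assert np.all(np.isfinite(maps.fw))
        np.testing.assert_allclose(maps.fw, 0.3, atol=0.02)


class TestCrossingFibers:
    def test_single_tensor_fa_and_mo_rise_when_one_bundle_removed(
            self, crossing_phantom, crossing_dti):
        """The mechanism behind paradoxically high FA_T near lesions:
        a crossing voxel fits a low-FA, oblate (MO ~ -1) tensor; deleting
        one bundle's contribution raises both FA and MO."""
        spec, data, truth = crossing_phantom
        fit = crossing_dti
        lam = fit.eigenvalues
        fa, _, mo = scalars_from_eigenvalues(lam[..., 0], lam[..., 1],
                                             lam[..., 2])
        cross = (truth.bundle_masks["CC_4"] & truth.bundle_masks["CST_right"]
                 & ~truth.lesion_mask)
        single = (truth.bundle_masks["CC_4"] & ~truth.bundle_masks["CST_right"]
                  & ~truth.lesion_mask)
        assert cross.sum() > 0 and single.sum() > 0
        assert np.nanmean(fa[single]) > np.nanmean(fa[cross]) + 0.2
        assert np.nanmean(mo[single]) > np.nanmean(mo[cross]) + 0.5
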