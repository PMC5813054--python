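"""Iterative CS reconstruction, GRAPPA fill and coil combination."""

import numpy as np
import pytest

from carotidcs.kspace import (
    KSpaceData,
    apply_mask,
    combine_masks,
    encode,
    fft3c,
    ifft3c,
    make_cs_mask,
    make_pi_mask,
)
from carotidcs.phantom import build_phantom
from carotidcs.recon import (
    ReconParams,
    ReconProblem,
    ReconResult,
    cs_fill,
    grappa_fill,
    nrmse,
    reconstruct,
    sos_combine,
    zero_fill_recon,
)
from conftest import small_spec


@pytest.fixture(scope="module")
def encoded_small():
    spec = small_spec()
    images, geom, sens = build_phantom(spec, contrasts=("t1w",))
    img = images["t1w"]
    k = encode(img, sens, noise_sd=0.0)
    ref = sos_combine(sens.maps * img[None])
    return spec, img, sens, k, ref


class TestZeroFill:
    def test_full_sampling_exact(self, encoded_small):
        spec, img, sens, k, ref = encoded_small
        imgs = zero_fill_recon(k)
        assert np.allclose(imgs, sens.maps * img[None], atol=1e-12)

    def test_linearity(self, encoded_small):
        _, _, _, k, _ = encoded_small
        k2 = KSpaceData(data=2.5 * k.data, mask=k.mask)
        assert np.allclose(zero_fill_recon(k2), 2.5 * zero_fill_recon(k), atol=1e-12)


class TestCsFill:
    def test_full_mask_equals_zero_fill(self, encoded_small):
        spec, img, sens, k, ref = encoded_small
        full = make_cs_mask(spec.grid_shape[1:], R=1.0, center=(16, 16), seed=0)
        ku = apply_mask(k, full)
        res = cs_fill(ReconProblem(kspace=ku, params=ReconParams(n_iter=3)))
        assert nrmse(res.combined, sos_combine(zero_fill_recon(ku))) <= 1e-10

    def test_hard_dc_after_every_iteration(self, encoded_small):
        spec, img, sens, k, ref = encoded_small
        mask = make_cs_mask(spec.grid_shape[1:], R=2.0, center=(16, 16), seed=3)
        ku = apply_mask(k, mask)
        sampled = mask.mask

        seen = []

        def check(it, m, km):
            seen.append(it)
            assert np.array_equal(km[:, :, sampled], ku.data[:, :, sampled])

        res = cs_fill(ReconProblem(kspace=ku, params=ReconParams()), iter_callback=check)
        assert seen == list(range(15))
        assert np.array_equal(res.coil_kspace[:, :, sampled], ku.data[:, :, sampled])
        assert res.data_residual == 0.0

    def test_cs_beats_zero_fill_noiseless(self, encoded_small):
        spec, img, sens, k, ref = encoded_small
        mask = make_cs_mask(spec.grid_shape[1:], R=2.0, center=(16, 16), seed=3)
        ku = apply_mask(k, mask)
        zf = sos_combine(zero_fill_recon(ku))
        res = cs_fill(ReconProblem(kspace=ku))
        assert nrmse(res.combined, ref) <= nrmse(zf, ref)

    def test_l1_trace_recorded(self, encoded_small):
        spec, _, _, k, _ = encoded_small
        mask = make_cs_mask(spec.grid_shape[1:], R=1.5, center=(16, 16), seed=1)
        res = cs_fill(ReconProblem(kspace=apply_mask(k, mask)))
        assert len(res.l1_trace) == 15
        assert np.all(res.l1_trace > 0)

    def test_soft_consistency_epsilon_ball(self, encoded_small):
        spec, _, _, k, _ = encoded_small
        mask = make_cs_mask(spec.grid_shape[1:], R=1.5, center=(16, 16), seed=1)
        ku = apply_mask(k, mask)
        res = cs_fill(ReconProblem(kspace=ku, params=ReconParams(eps=0.5, n_iter=4)))
        assert res.data_residual <= 0.5 + 1e-9


class TestGrappa:
    def test_single_coil_rejected(self, encoded_small):
        spec, _, _, k, _ = encoded_small
        pi = make_pi_mask(spec.grid_shape[1:], factors=(2, 1), calib=(16, 16))
        one = KSpaceData(data=k.data[:1], mask=pi)
        with pytest.raises(ValueError, match="2 coils"):
            grappa_fill(one)

    def test_fully_sampled_untouched(self, encoded_small):
        _, _, _, k, _ = encoded_small
        out = grappa_fill(k)
        assert out is k

    def test_uniform_r2_fill_quality(self, encoded_small):
        """Noiseless smooth 4-coil data, uniform R=2: filled k-space within
        5% NRMSE of the fully sampled truth."""
        spec, img, sens, k, ref = encoded_small
        pi = make_pi_mask(spec.grid_shape[1:], factors=(2, 1), calib=(24, 16))
        ku = apply_mask(k, pi)
        filled = grappa_fill(ku, kernel=(5, 4))
        assert nrmse(filled.data, k.data) < 0.05
        # acquired comb lines and CS/calib values are untouched
        assert np.array_equal(filled.data[:, :, pi.mask], ku.data[:, :, pi.mask])

    def test_combined_mask_fills_only_pi_gaps(self, encoded_small):
        spec, img, sens, k, ref = encoded_small
        cs = make_cs_mask(spec.grid_shape[1:], R=1.5, center=(16, 16), seed=2)
        pi = make_pi_mask(spec.grid_shape[1:], factors=(2, 1), calib=(16, 16))
        comb = combine_masks(cs, pi)
        ku = apply_mask(k, comb)
        res = cs_fill(ReconProblem(kspace=ku))
        after_cs = KSpaceData(data=res.coil_kspace, mask=comb)
        filled = grappa_fill(after_cs)
        keep = pi.mask  # CS-filled values on comb-sampled lines are untouched
        assert np.array_equal(filled.data[:, :, keep], after_cs.data[:, :, keep])
        gaps = ~pi.mask
        assert not np.array_equal(filled.data[:, :, gaps], after_cs.data[:, :, gaps])


class TestSosCombine:
    def test_single_coil_is_magnitude(self, rng):
        img = rng.standard_normal((4, 5, 6)) + 1j * rng.standard_normal((4, 5, 6))
        assert np.allclose(sos_combine(img[None]), np.abs(img))

    def test_two_identical_coils(self, rng):
        img = rng.standard_normal((4, 5, 6)) + 1j * rng.standard_normal((4, 5, 6))
        two = np.stack([img, img])
        assert np.allclose(sos_combine(two), np.sqrt(2) * np.abs(img))

    def test_phase_invariance(self, rng):
        imgs = rng.standard_normal((3, 4, 5, 6)) + 1j * rng.standard_normal((3, 4, 5, 6))
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, 3))
        rotated = imgs * phases[:, None, None, None]
        assert np.allclose(sos_combine(rotated), sos_combine(imgs), atol=1e-12)


class TestReconstruct:
    def test_full_sampling_machine_precision(self, encoded_small):
        spec, img, sens, k, ref = encoded_small
        res = reconstruct(k)
        assert nrmse(res.combined, ref) <= 1e-10

    def test_determinism(self, encoded_small):
        spec, img, sens, k, ref = encoded_small
        mask = make_cs_mask(spec.grid_shape[1:], R=2.0, center=(16, 16), seed=5)
        ku = apply_mask(k, mask)
        a = reconstruct(ku)
        b = reconstruct(ku)
        assert np.array_equal(a.combined, b.combined)

    def test_combined_cs_pi_beats_zero_fill(self, encoded_small):
        spec, img, sens, k, ref = encoded_small
        cs = make_cs_mask(spec.grid_shape[1:], R=1.5, center=(16, 16), seed=2)
        pi = make_pi_mask(spec.grid_shape[1:], factors=(2, 1), calib=(16, 16))
        comb = combine_masks(cs, pi)
        ku = apply_mask(k, comb)
        res = reconstruct(ku)
        zf = sos_combine(zero_fill_recon(ku))
        assert nrmse(res.combined, ref) <= nrmse(zf, ref)

    def test_nrmse_monotone_in_R(self):
        """Median error grows with acceleration; CS stays at or below
        zero-fill for every undersampled factor."""
        spec = small_spec()
        med_zf, med_cs = {}, {}
        for R in (1.0, 1.5, 2.0):
            errs_zf, errs_cs = [], []
            for seed in range(4):
                s = small_spec(lumen_radius_mm=2.6 + 0.2 * seed)
                images, _, sens = build_phantom(s, contrasts=("t1w",))
                k = encode(images["t1w"], sens, noise_sd=0.0, seed=seed)
                ref = sos_combine(sens.maps * images["t1w"][None])
                mask = make_cs_mask(s.grid_shape[1:], R=R, center=(16, 16), seed=seed)
                ku = apply_mask(k, mask)
                errs_zf.append(nrmse(sos_combine(zero_fill_recon(ku)), ref))
                errs_cs.append(nrmse(reconstruct(ku).combined, ref))
                if R > 1:
                    assert errs_cs[-1] <= errs_zf[-1]
            med_zf[R], med_cs[R] = np.median(errs_zf), np.median(errs_cs)
        assert med_zf[1.0] <= med_zf[1.5] <= med_zf[2.0]
        assert med_cs[1.0] <= med_cs[1.5] <= med_cs[2.0]


class TestNrmse:
    def test_basic_values(self, rng):
        ref = rng.standard_normal((5, 5))
        assert nrmse(ref, ref) == 0.0
        assert nrmse(2 * ref, ref) == pytest.approx(1.0)
        e = rng.standard_normal((5, 5))
        assert nrmse(ref + e, ref) == pytest.approx(np.linalg.norm(e) / np.linalg.norm(ref))

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="zero"):
            nrmse(np.ones((2, 2)), np.zeros((2, 2)))
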