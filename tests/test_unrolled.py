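"""Unrolled reconstruction: exactness limits, priors, metrics, training."""

import numpy as np
import pytest

from llrpdff.llr import back_project, local_bases, project
from llrpdff.phantom import make_coils, make_mask, simulate_kspace
from llrpdff.sense import SenseSystem
from llrpdff.unrolled import (
    ReconConfig,
    TrainConfig,
    evaluate_reconstruction,
    make_training_pairs,
    reconstruct,
    svt_prior,
    train,
    zero_filled,
)


class TestReconstruct:
    def test_identity_denoiser_exact_on_fully_sampled_noiseless(self, small_study):
        shape = small_study["shape"]
        mask = make_mask(shape[:2], 1)
        coils = small_study["coils"]
        system = SenseSystem(coils, mask)
        ksp = simulate_kspace(
            small_study["phantom"],
            small_study["spectrum"],
            small_study["echoes"],
            coils,
            mask,
            0.0,
            0,
        )
        out = reconstruct(ksp, system, ReconConfig(n_iter=2, lam=1e6, denoiser="identity"))
        ref = small_study["reference"].data
        assert np.linalg.norm(out.data - ref) / np.linalg.norm(ref) < 1e-5

    def test_single_iteration_is_plain_regularized_sense(self, small_study):
        system = SenseSystem(small_study["coils"], small_study["mask"])
        ksp = small_study["kspace"]
        out = reconstruct(
            ksp, system, ReconConfig(n_iter=1, lam=1.5, denoiser="svt", normalize=False)
        )
        direct = system.solve_regularized(ksp.data, prior=0.0, lam=1.5)
        np.testing.assert_allclose(out.data, direct, atol=1e-12)

    def test_svt_prior_beats_zero_filled(self, small_study):
        """Criterion: the regularized unroll must outperform the adjoint."""
        system = SenseSystem(small_study["coils"], small_study["mask"])
        recon = reconstruct(
            small_study["kspace"],
            system,
            ReconConfig(denoiser="svt", lam=(1, 2, 4, 8, 8, 8)),
        )
        ref = small_study["reference"]
        psnr_svt, _ = evaluate_reconstruction(recon, ref)
        psnr_zf, _ = evaluate_reconstruction(zero_filled(small_study["kspace"], system), ref)
        assert psnr_svt > psnr_zf

    def test_reconstruction_is_idempotent(self, small_study):
        system = SenseSystem(small_study["coils"], small_study["mask"])
        cfg = ReconConfig(n_iter=2, denoiser="svt")
        a = reconstruct(small_study["kspace"], system, cfg)
        b = reconstruct(small_study["kspace"], system, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_final_solve_anchors_data_consistency(self, small_study):
        """The last solve pulls the prior toward the acquired samples."""
        system = SenseSystem(small_study["coils"], small_study["mask"])
        ksp = small_study["kspace"]
        a = ksp.data
        z = 0.0
        lam = 2.0
        for _ in range(2):
            m = system.solve_regularized(a, prior=z, lam=lam)
            bases = local_bases(m)
            z = back_project(svt_prior(project(m, bases), ("hard", 2)))
        m_final = system.solve_regularized(a, prior=z, lam=lam)
        res_final = np.linalg.norm(system.apply(m_final) - a)
        res_prior = np.linalg.norm(system.apply(z) - a)
        assert res_final <= res_prior + 1e-12


class TestSvtPriorRules:
    def test_hard_full_rank_is_identity(self, small_study, rng):
        img = rng.standard_normal((6, 1, 8, 8)) + 1j * rng.standard_normal((6, 1, 8, 8))
        p = project(img, local_bases(img))
        out = svt_prior(p, ("hard", 6))
        np.testing.assert_array_equal(out.coefficients, p.coefficients)

    def test_hard_rank_zero_is_zero(self, rng):
        img = rng.standard_normal((4, 1, 6, 6)) + 0j
        p = project(img, local_bases(img))
        assert np.all(svt_prior(p, ("hard", 0)).coefficients == 0)

    def test_rank_cut_beyond_components_rejected(self, rng):
        img = rng.standard_normal((4, 1, 6, 6)) + 0j
        p = project(img, local_bases(img))
        with pytest.raises(ValueError):
            svt_prior(p, ("hard", 5))

    def test_soft_rule_shrinks_tail_components(self, rng):
        img = rng.standard_normal((4, 1, 10, 10)) + 1j * rng.standard_normal((4, 1, 10, 10))
        p = project(img, local_bases(img))
        out = svt_prior(p, ("soft", 0.3))
        assert np.all(np.abs(out.coefficients) <= np.abs(p.coefficients) + 1e-12)


class TestEvaluateReconstruction:
    def test_identical_images(self, small_study):
        ref = small_study["reference"]
        psnr, ssim = evaluate_reconstruction(ref, ref)
        assert psnr == np.inf and ssim == pytest.approx(1.0)

    def test_uniform_offset_closed_form(self):
        ref = np.zeros((1, 1, 32, 32))
        ref[0, 0, 8:24, 8:24] = 1.0  # unit-peak reference
        d = 0.05
        psnr, _ = evaluate_reconstruction(ref + d, ref)
        assert psnr == pytest.approx(-20 * np.log10(d), abs=1e-9)

    def test_ssim_decreases_with_noise_strength(self, small_study, rng):
        ref = small_study["reference"].data
        weak = ref + 0.01 * rng.standard_normal(ref.shape)
        strong = ref + 0.2 * rng.standard_normal(ref.shape)
        _, s_weak = evaluate_reconstruction(weak, ref)
        _, s_strong = evaluate_reconstruction(strong, ref)
        assert s_strong < s_weak


class TestTraining:
    def test_validation_loss_decreases_and_is_deterministic(
        self, nine_peak, protocol1
    ):
        pairs = make_training_pairs(
            5, (2, 16, 16), protocol1, nine_peak, n_coils=4, seed=1
        )
        cfg = TrainConfig(epochs=2, base_features=4, n_pools=2)
        net, hist = train(pairs, cfg, seed=0)
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        _, hist2 = train(pairs, cfg, seed=0)
        assert hist2["val_loss"] == hist["val_loss"]
        assert hist2["train_loss"] == hist["train_loss"]

    def test_split_fractions(self, nine_peak, protocol1):
        pairs = make_training_pairs(
            5, (2, 16, 16), protocol1, nine_peak, n_coils=4, seed=1
        )
        _, hist = train(pairs, TrainConfig(epochs=1, base_features=4, n_pools=2), seed=0)
        s = hist["splits"]
        assert len(s["train"]) + len(s["val"]) + len(s["test"]) == len(pairs)
        assert set(s["train"]).isdisjoint(s["val"])
        assert set(s["train"]).isdisjoint(s["test"])

    def test_learned_denoiser_runs_in_reconstruction(self, small_study, nine_peak):
        pairs = make_training_pairs(
            3, (2, 32, 32), small_study["echoes"], nine_peak, n_coils=4, seed=2
        )
        net, _ = train(pairs, TrainConfig(epochs=1, base_features=4, n_pools=2), seed=0)
        system = SenseSystem(small_study["coils"], small_study["mask"])
        out = reconstruct(
            small_study["kspace"],
            system,
            ReconConfig(n_iter=2, denoiser="learned"),
            network=net,
        )
        assert np.all(np.isfinite(out.data))

    def test_learned_denoiser_without_weights_rejected(self, small_study):
        system = SenseSystem(small_study["coils"], small_study["mask"])
        with pytest.raises(ValueError):
            reconstruct(
                small_study["kspace"], system, ReconConfig(denoiser="learned")
            )
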