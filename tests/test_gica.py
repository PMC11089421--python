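"""Group ICA stages: PCA oracles, infomax source recovery, ICASSO, spectra."""

import numpy as np
import pytest

from dynconn.gica import (
    GroupICAResult,
    back_reconstruct,
    group_pca_concat,
    icasso_stability,
    infomax_ica,
    match_components,
    spectral_icn_metrics,
    subject_pca,
)
from dynconn.simulate import SubjectTimeSeries

TR = 0.906


def ts(data, sid="s1"):
    return SubjectTimeSeries(data=data, tr_seconds=TR, subject_id=sid)


def super_gaussian_sources(n, samples, rng):
    """Sparse (Laplace-like) sources, as spatial ICN maps are."""
    return rng.laplace(size=(n, samples)) ** 3 / 10 + rng.laplace(size=(n, samples))


class TestSubjectPCA:
    def test_rank2_explains_everything(self, rng):
        basis = rng.normal(size=(2, 40))
        data = rng.normal(size=(30, 2)) @ basis  # voxels x time, rank 2
        data -= data.mean(axis=1, keepdims=True)  # keep rank 2 after demeaning
        pca = subject_pca(ts(data), 2)
        assert pca.explained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_trace_conservation(self, rng):
        data = rng.normal(size=(50, 30))
        pca = subject_pca(ts(data), 10)
        demeaned = data - data.mean(axis=1, keepdims=True)
        assert pca.eigenvalues.sum() == pytest.approx((demeaned ** 2).sum())

    def test_components_ordered_by_variance(self, rng):
        pca = subject_pca(ts(rng.normal(size=(60, 40))), 20)
        assert (np.diff(pca.eigenvalues) <= 1e-9).all()

    def test_exceeding_rank_names_achievable_rank(self, rng):
        basis = rng.normal(size=(3, 40))
        data = rng.normal(size=(30, 3)) @ basis
        data -= data.mean(axis=1, keepdims=True)
        with pytest.raises(ValueError, match="rank"):
            subject_pca(ts(data), 10)

    def test_planted_factor_reconstruction(self, rng):
        factors = rng.normal(size=(3, 100))
        load = rng.normal(size=(80, 3))
        data = load @ factors + 0.01 * rng.normal(size=(80, 100))
        pca = subject_pca(ts(data), 3)
        recon = (pca.basis @ pca.reduced).T  # voxels x time
        demeaned = data - data.mean(axis=1, keepdims=True)
        r = np.corrcoef(recon.ravel(), demeaned.ravel())[0, 1]
        assert r > 0.99


class TestGroupPCA:
    def make_subjects(self, rng, n=3, t=40, v=60, n_pc=10):
        return [
            subject_pca(ts(rng.normal(size=(v, t)), f"s{i}"), n_pc) for i in range(n)
        ]

    def test_single_subject_matches_direct_pca(self, rng):
        subs = self.make_subjects(rng, n=1)
        gp = group_pca_concat(subs, 5, method="svd")
        # group step on one subject = further PCA of its reduced data
        u, _, _ = np.linalg.svd(subs[0].reduced, full_matrices=False)
        overlap = np.linalg.svd(gp.basis.T @ u[:, :5], compute_uv=False)
        np.testing.assert_allclose(overlap, 1.0, atol=1e-8)

    def test_duplicated_subject_spans_same_subspace(self, rng):
        subs = self.make_subjects(rng, n=1)
        dup = subs + subs
        g1 = group_pca_concat(subs, 4, method="svd").reduced
        g2 = group_pca_concat(dup, 4, method="svd").reduced
        # identical voxel-space row span
        r1 = np.linalg.matrix_rank(np.vstack([g1, g2]), tol=1e-8)
        assert r1 == 4

    def test_em_matches_exact_eigendecomposition(self, rng):
        subs = self.make_subjects(rng, n=4)
        em = group_pca_concat(subs, 6, method="em", seed=0)
        svd = group_pca_concat(subs, 6, method="svd")
        overlap = np.linalg.svd(em.basis.T @ svd.basis, compute_uv=False)
        angles = np.arccos(np.clip(overlap, -1, 1))
        assert angles.max() < 1e-3

    def test_inconsistent_voxel_dimension_rejected(self, rng):
        a = subject_pca(ts(rng.normal(size=(60, 40)), "a"), 5)
        b = subject_pca(ts(rng.normal(size=(50, 40)), "b"), 5)
        with pytest.raises(ValueError, match="voxel"):
            group_pca_concat([a, b], 4)


class TestInfomax:
    def test_recovers_planted_super_gaussian_sources(self, rng):
        s = super_gaussian_sources(3, 2000, rng)
        a = rng.normal(size=(3, 3))
        x = a @ s
        est, mixing, converged = infomax_ica(x, 3, seed=0)
        _, cors = match_components(est, s)
        assert cors.min() > 0.95

    def test_orthogonal_mixing_gives_signed_permutation(self, rng):
        s = super_gaussian_sources(2, 3000, rng)
        s = (s - s.mean(axis=1, keepdims=True)) / s.std(axis=1, keepdims=True)
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        est, _, _ = infomax_ica(q @ s, 2, seed=1)
        c = (est @ s.T) / s.shape[1]  # near signed permutation
        c_abs = np.abs(c)
        assert c_abs.max(axis=1).min() > 0.95
        assert c_abs.min() < 0.2

    def test_single_component_is_first_principal_direction(self, rng):
        x = rng.normal(size=(4, 500))
        x[0] *= 5.0  # dominant direction
        est, _, _ = infomax_ica(x, 1, seed=0)
        u, _, _ = np.linalg.svd(x - x.mean(axis=1, keepdims=True), full_matrices=False)
        pc1 = u[:, 0] @ (x - x.mean(axis=1, keepdims=True))
        r = abs(np.corrcoef(est[0], pc1)[0, 1])
        assert r > 0.999

    def test_mixing_reconstructs_data(self, rng):
        s = super_gaussian_sources(3, 1500, rng)
        x = rng.normal(size=(5, 3)) @ s
        est, mixing, _ = infomax_ica(x, 3, seed=2)
        recon = mixing @ est
        xc = x - x.mean(axis=1, keepdims=True)
        assert np.corrcoef(recon.ravel(), xc.ravel())[0, 1] > 0.99


class TestICASSO:
    def test_clean_mixture_gives_high_iq(self, rng):
        from dynconn.gica import GroupPCA

        s = super_gaussian_sources(4, 2000, rng)
        x = rng.normal(size=(6, 4)) @ s
        gp = GroupPCA(reduced=x, basis=np.eye(6), block_slices=[slice(0, 6)])
        res = icasso_stability(gp, 4, n_runs=5, seed=0)
        assert res.stability_iq.min() > 0.9
        assert res.n_ica_runs == 5

    def test_retention_threshold_is_strict(self):
        res = GroupICAResult(
            group_maps=np.zeros((2, 5)), mixing=np.zeros((2, 2)),
            stability_iq=np.array([0.79, 0.81]), n_subject_pcs=2, n_group_pcs=2,
            n_ica_runs=2,
        )
        assert res.retained.tolist() == [False, True]

    def test_too_few_runs_rejected(self, rng):
        from dynconn.gica import GroupPCA

        gp = GroupPCA(reduced=rng.normal(size=(3, 100)), basis=np.eye(3),
                      block_slices=[slice(0, 3)])
        with pytest.raises(ValueError, match="n_runs"):
            icasso_stability(gp, 2, n_runs=1)


class TestBackReconstruction:
    def test_single_subject_group_recovers_maps(self, rng):
        # enough voxels that spatial ICA has the samples it needs
        maps = rng.laplace(size=(3, 2000))
        courses = rng.normal(size=(3, 60))
        data = maps.T @ courses + 0.01 * rng.normal(size=(2000, 60))
        subj = ts(data)
        spca = subject_pca(subj, 10)
        gp = group_pca_concat([spca], 6, method="svd")
        res = icasso_stability(gp, 3, n_runs=4, seed=0)
        back_reconstruct(res, gp, [spca], [subj])
        _, map_cors = match_components(res.subject_maps["s1"], maps)
        assert map_cors.min() > 0.95
        perm, tc_cors = match_components(
            res.subject_timecourses["s1"].T, courses
        )
        assert tc_cors.min() > 0.95

    def test_zero_variance_subject_rejected(self, rng):
        subj_ok = ts(rng.normal(size=(50, 40)), "ok")
        spca = subject_pca(subj_ok, 5)
        gp = group_pca_concat([spca], 3, method="svd")
        res = icasso_stability(gp, 2, n_runs=3, seed=0)
        flat = SubjectTimeSeries(
            data=np.zeros((50, 40)) + 1.0, tr_seconds=TR, subject_id="flat"
        )
        with pytest.raises(ValueError, match="zero-variance"):
            back_reconstruct(res, gp, [spca], [flat])


class TestSpectralMetrics:
    def sinusoid(self, freq, n=295, noise=1e-3, seed=0):
        t = np.arange(n) * TR
        rng = np.random.default_rng(seed)
        return np.sin(2 * np.pi * freq * t) + noise * rng.normal(size=n)

    def test_low_frequency_dominated(self):
        m = spectral_icn_metrics(self.sinusoid(0.05), TR)
        assert m.power_ratio > 10
        assert m.is_icn

    def test_noise_band_dominated(self):
        m = spectral_icn_metrics(self.sinusoid(0.20), TR)
        assert m.power_ratio < 0.5
        assert not m.is_icn

    def test_white_noise_ratio_near_band_width_ratio(self):
        ratios = [
            spectral_icn_metrics(
                np.random.default_rng(seed).normal(size=2048), TR
            ).power_ratio
            for seed in range(20)
        ]
        assert 0.7 < np.mean(ratios) < 1.4

    def test_nyquist_below_band_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_icn_metrics(np.zeros(128), tr_seconds=3.0)
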