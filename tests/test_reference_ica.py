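"""Reference-guided subject ICA: objectives, gradients, recovery."""

import numpy as np
import pytest

from rinan.containers import BoldRun, SpatialMap
from rinan.reference_ica import (GigIcaConfig, ReferenceSet, _CONTRASTS,
                                 _gaussian_expectation, _gradient,
                                 _objective_parts, cica_subject, closeness,
                                 compute_tc, gig_ica_subject, negentropy_proxy,
                                 whiten_run)
from rinan.simulate import SimulationConfig, generate_guided_cohort


class TestNegentropyProxy:
    def test_gaussian_sample_is_nearly_zero(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(10 ** 6)
        y = (y - y.mean()) / y.std()
        assert negentropy_proxy(y) < 1e-4

    def test_rademacher_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.choice([-1.0, 1.0], size=200_000)
        # independent oracle: closed-form G(+-1) minus a huge Gaussian sample
        z = np.random.default_rng(2).standard_normal(10 ** 7)
        oracle = (np.log(np.cosh(1.0)) - np.mean(np.logaddexp(z, -z)
                                                 - np.log(2.0))) ** 2
        assert abs(negentropy_proxy(y) - oracle) < 1e-3

    def test_sign_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.laplace(size=5000)
        y = (y - y.mean()) / y.std()
        assert negentropy_proxy(y) == pytest.approx(negentropy_proxy(-y))

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            negentropy_proxy(np.array([1.0, np.nan]))

    def test_gaussian_constant_matches_quadrature(self):
        # E[log cosh z] for z ~ N(0,1); literature value ~ 0.3746
        assert _gaussian_expectation("logcosh") == pytest.approx(0.374567,
                                                                 abs=1e-5)
        assert _gaussian_expectation("kurtosis") == pytest.approx(3.0,
                                                                  abs=1e-9)


class TestCloseness:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(4)
        r = rng.standard_normal(1000)
        r = (r - r.mean()) / r.std()
        assert closeness(r, r) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(1000)
        y = (y - y.mean()) / y.std()
        assert closeness(y, -y) == pytest.approx(-1.0)

    def test_orthogonal_construction_is_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        r = np.array([1.0, 1.0, -1.0, -1.0])
        assert abs(closeness(y, r)) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            closeness(np.zeros(3), np.zeros(4))


class TestComputeTc:
    def test_uniform_map_gives_voxel_mean_series(self, random_run):
        ones = SpatialMap(np.ones(random_run.n_voxels), random_run.mask_index,
                          random_run.grid)
        assert np.allclose(compute_tc(random_run, ones),
                           random_run.data.mean(axis=1))

    def test_delta_weight_extracts_single_voxel(self, random_run):
        v = 11
        w = np.zeros(random_run.n_voxels)
        w[v] = random_run.n_voxels
        delta = SpatialMap(w, random_run.mask_index, random_run.grid)
        assert np.allclose(compute_tc(random_run, delta),
                           random_run.data[:, v])

    def test_matches_per_voxel_loop(self, random_run, random_zmap):
        vec = compute_tc(random_run, random_zmap)
        loop = np.zeros(random_run.n_time)
        for v in range(random_run.n_voxels):
            loop += random_zmap.values[v] * random_run.data[:, v]
        loop /= random_run.n_voxels
        assert np.abs(vec - loop).max() < 1e-12


@pytest.fixture(scope="module")
def guided():
    cfg = SimulationConfig(grid_dims=(10, 10, 10), n_time=150,
                           n_sources=4, noise_sd=0.2,
                           n_subjects_per_group=1, seed=21)
    return generate_guided_cohort(cfg, reference_r=0.8)


class TestOptimizer:
    def test_gradient_matches_finite_differences(self, guided):
        cfgs = GigIcaConfig()
        Xw, _ = whiten_run(guided.runs[0], 4)
        r = guided.references[0].values
        rng = np.random.default_rng(0)
        w = rng.standard_normal(4)
        w /= np.linalg.norm(w)
        y, diff, Q, K, C, F = _objective_parts(w, Xw, r, cfgs)
        g = _gradient(w, Xw, y, diff, Q, r, cfgs)
        eps = 1e-6
        for k in range(4):
            wp, wm = w.copy(), w.copy()
            wp[k] += eps
            wm[k] -= eps
            fp = _objective_parts(wp, Xw, r, cfgs)[5]
            fm = _objective_parts(wm, Xw, r, cfgs)[5]
            assert g[k] == pytest.approx((fp - fm) / (2 * eps), abs=1e-5)

    def test_objective_trace_non_decreasing(self, guided):
        res = gig_ica_subject(guided.runs[0], ReferenceSet(guided.references))
        for trace in res.objective_trace:
            assert np.all(np.diff(trace) >= -1e-12)

    def test_unmixing_vectors_unit_norm(self, guided):
        res = gig_ica_subject(guided.runs[0], ReferenceSet(guided.references))
        norms = np.linalg.norm(res.unmixing_vectors, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-10

    def test_time_courses_equal_compute_tc(self, guided):
        run = guided.runs[0]
        res = gig_ica_subject(run, ReferenceSet(guided.references))
        for i, m in enumerate(res.maps):
            assert np.array_equal(res.time_courses[i], compute_tc(run, m))

    def test_arctan_normalised_objective_bounded(self, guided):
        cfgs = GigIcaConfig()
        Xw, _ = whiten_run(guided.runs[0], 4)
        r = guided.references[0].values
        rng = np.random.default_rng(1)
        for _ in range(20):
            w = rng.standard_normal(4)
            w /= np.linalg.norm(w)
            K = _objective_parts(w, Xw, r, cfgs)[3]
            assert 0.0 <= K < 1.0

    def test_recovered_map_closer_to_subject_truth_than_reference(self, guided):
        res = gig_ica_subject(guided.runs[0], ReferenceSet(guided.references))
        for i, m in enumerate(res.maps):
            r_truth = np.corrcoef(m.values,
                                  guided.subject_maps[0][i].values)[0, 1]
            r_ref = np.corrcoef(m.values, guided.references[i].values)[0, 1]
            assert r_truth >= r_ref
            assert r_truth > 0.9

    def test_high_a_limit_matches_one_unit_fastica(self):
        # a -> 1: the most non-Gaussian direction, independently found by
        # FastICA, should coincide with the guided solution
        from sklearn.decomposition import FastICA

        rng = np.random.default_rng(9)
        n_vox = 4000
        S = np.vstack([rng.laplace(size=n_vox), rng.standard_normal(n_vox)])
        from rinan.containers import MaskIndex, VolumeGrid

        dims = (20, 20, 10)
        idx = MaskIndex(np.ones(dims, dtype=bool))
        grid = VolumeGrid(dims)
        A = rng.standard_normal((30, 2))
        run = BoldRun(A @ S, idx, grid)
        ref_noisy = S[0] + 0.5 * rng.standard_normal(n_vox)
        ref = SpatialMap(ref_noisy, idx, grid, label="ref")
        res = gig_ica_subject(run, ReferenceSet([ref]),
                              GigIcaConfig(a=0.999))
        fica = FastICA(n_components=1, fun="logcosh", random_state=0,
                       whiten="unit-variance")
        comp = fica.fit_transform(run.data.T)[:, 0]
        r = np.corrcoef(res.maps[0].values, comp)[0, 1]
        assert abs(r) > 0.99

    def test_default_weighting_is_half(self):
        assert GigIcaConfig().a == 0.5

    def test_cica_is_the_same_code_path(self):
        assert cica_subject is gig_ica_subject

    def test_all_zero_reference_rejected(self, guided):
        ref0 = guided.references[0]
        zero = SpatialMap(np.zeros(ref0.n_voxels), ref0.mask_index, ref0.grid,
                          label="flat")
        with pytest.raises(ValueError, match="zero"):
            gig_ica_subject(guided.runs[0], ReferenceSet([zero]))
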