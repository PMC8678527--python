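"""Component screening: tissue priors, spectral ratio, ICN matching, peaks."""

import itertools

import numpy as np
import pytest

from rinan.containers import MaskIndex, SpatialMap, VolumeGrid
from rinan.reference_ica import ReferenceSet
from rinan.select import (RATIO_CAP, match_to_icns, peak_coordinate,
                          screen_components, spectral_ratio, tissue_screen)
from rinan.simulate import SimulationConfig, generate_sources


def _flat_setup(dims=(8, 8, 8)):
    return MaskIndex(np.ones(dims, dtype=bool)), VolumeGrid(dims)


def _blob(idx, grid, center, radius, label=""):
    d = np.linalg.norm(idx.voxels - np.asarray(center), axis=1)
    return SpatialMap((d <= radius).astype(float), idx, grid, label=label)


class TestTissueScreen:
    def test_gm_like_component_retained(self):
        idx, grid = _flat_setup()
        gm = _blob(idx, grid, (2, 2, 2), 2.5, "gm")
        csf = _blob(idx, grid, (6, 6, 6), 1.5, "csf")
        df = tissue_screen([gm], gm, None, csf)
        assert df.loc[0, "gm_r"] == pytest.approx(1.0)
        assert bool(df.loc[0, "tissue_pass"])

    def test_csf_like_component_excluded(self):
        idx, grid = _flat_setup()
        gm = _blob(idx, grid, (2, 2, 2), 2.5)
        csf = _blob(idx, grid, (6, 6, 6), 1.5)
        df = tissue_screen([csf], gm, None, csf)
        assert not bool(df.loc[0, "tissue_pass"])

    def test_disjoint_gray_blob_passes_with_negative_csf_r(self):
        idx, grid = _flat_setup()
        gm = _blob(idx, grid, (2, 2, 2), 2.5)
        csf = _blob(idx, grid, (6, 6, 6), 1.5)
        comp = _blob(idx, grid, (2, 2, 3), 2.5)  # overlaps GM, not CSF
        df = tissue_screen([comp], gm, None, csf)
        assert df.loc[0, "gm_r"] > 0
        assert df.loc[0, "csf_r"] <= 0
        assert bool(df.loc[0, "tissue_pass"])

    def test_missing_priors_skip_criterion(self):
        idx, grid = _flat_setup()
        comp = _blob(idx, grid, (4, 4, 4), 2.0)
        df = tissue_screen([comp], None, None, None)
        assert bool(df.loc[0, "tissue_pass"])


class TestSpectralRatio:
    def test_low_frequency_sinusoid_hits_the_cap(self):
        t = np.arange(200) * 2.0  # TR = 2 s
        tc = np.sin(2 * np.pi * 0.05 * t)
        assert spectral_ratio(tc, 2.0, 0.1) == RATIO_CAP

    def test_high_frequency_sinusoid_near_zero(self):
        t = np.arange(200) * 2.0
        tc = np.sin(2 * np.pi * 0.2 * t)
        assert spectral_ratio(tc, 2.0, 0.1) < 0.01

    def test_white_noise_matches_bandwidth_ratio(self):
        rng = np.random.default_rng(0)
        tc = rng.standard_normal(100_000)
        # flat spectrum at TR=2 s: (0, 0.1] vs (0.1, 0.25] -> 0.1/0.15
        assert spectral_ratio(tc, 2.0, 0.1) == pytest.approx(0.1 / 0.15,
                                                             abs=0.05)

    def test_split_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_ratio(np.zeros(100), 2.0, split_hz=0.3)


@pytest.fixture(scope="module")
def icn_maps():
    cfg = SimulationConfig(grid_dims=(10, 10, 10), n_sources=8, seed=13)
    maps = [m.zscored(label=f"ICN{i}")
            for i, (m, _) in enumerate(generate_sources(cfg))]
    return ReferenceSet(maps)


class TestMatchToIcns:
    def test_permuted_copies_recovered_exactly(self, icn_maps):
        perm = [3, 1, 4, 0, 2, 7, 5, 6]
        cands = [icn_maps.references[p] for p in perm]
        assignment, corrs, _ = match_to_icns(cands, icn_maps)
        for icn_idx, cand_idx in assignment.items():
            assert perm[cand_idx] == icn_idx
            assert corrs[icn_idx] == pytest.approx(1.0)

    def test_sign_flips_recovered_and_corrected(self, icn_maps):
        perm = [2, 0, 1, 3, 5, 4, 7, 6]
        cands = []
        for j, p in enumerate(perm):
            src = icn_maps.references[p]
            sign = -1.0 if j % 2 else 1.0
            cands.append(SpatialMap(sign * src.values, src.mask_index,
                                    src.grid))
        assignment, corrs, signed = match_to_icns(cands, icn_maps)
        for icn_idx, cand_idx in assignment.items():
            assert perm[cand_idx] == icn_idx
        for icn_idx, m in enumerate(signed):
            r = np.corrcoef(m.values,
                            icn_maps.references[icn_idx].values)[0, 1]
            assert r == pytest.approx(1.0)

    def test_optimal_assignment_matches_brute_force_under_noise(self,
                                                                icn_maps):
        # SNR ~ 2 noisy copies: optimal (Hungarian) vs exhaustive search
        refs = icn_maps.references
        agreement = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cands = [SpatialMap(r.values + 0.5 * rng.standard_normal(
                r.n_voxels), r.mask_index, r.grid) for r in refs]
            assignment, _, _ = match_to_icns(cands, icn_maps)
            C = np.abs(np.corrcoef(
                np.vstack([r.values for r in refs]
                          + [c.values for c in cands]))[:8, 8:])
            best, best_perm = -np.inf, None
            for perm in itertools.permutations(range(8)):
                tot = sum(C[i, perm[i]] for i in range(8))
                if tot > best:
                    best, best_perm = tot, perm
            hits = sum(assignment[i] == best_perm[i] for i in range(8))
            agreement += hits >= 7
        assert agreement == 50  # optimal solver always finds the optimum


class TestPeakCoordinate:
    def test_delta_map_peak_at_known_voxel(self):
        idx, grid = _flat_setup()
        v = np.zeros(idx.n_voxels)
        target = 100
        v[target] = 5.0
        ijk, world, value = peak_coordinate(SpatialMap(v, idx, grid))
        assert np.array_equal(ijk, idx.voxels[target])
        assert value == 5.0

    def test_tie_broken_by_lower_linear_index(self):
        idx, grid = _flat_setup()
        v = np.zeros(idx.n_voxels)
        v[[40, 300]] = 2.0
        ijk, _, _ = peak_coordinate(SpatialMap(v, idx, grid))
        assert np.array_equal(ijk, idx.voxels[40])

    def test_sphere_source_peaks_at_center(self):
        cfg = SimulationConfig(grid_dims=(10, 10, 10), n_sources=1, seed=2)
        m, core = generate_sources(cfg)[0]
        ijk, _, value = peak_coordinate(m)
        flat = np.flatnonzero(core)
        assert value == cfg.core_amplitude
        assert any(np.array_equal(ijk, m.mask_index.voxels[f]) for f in flat)

    def test_all_equal_map_warns_and_returns_first_voxel(self):
        idx, grid = _flat_setup()
        with pytest.warns(UserWarning, match="all-equal"):
            ijk, _, _ = peak_coordinate(
                SpatialMap(np.ones(idx.n_voxels), idx, grid))
        assert np.array_equal(ijk, idx.voxels[0])


class TestFullScreen:
    def test_planted_networks_selected_noise_rejected(self):
        # 8 planted blob networks + 4 noise components; the full screen
        # must select exactly the 8 planted ones
        cfg = SimulationConfig(grid_dims=(10, 10, 10), n_sources=8, seed=3)
        planted = [m.zscored(label=f"net{i}")
                   for i, (m, _) in enumerate(generate_sources(cfg))]
        idx, grid = planted[0].mask_index, planted[0].grid
        rng = np.random.default_rng(4)
        noise = [SpatialMap(rng.standard_normal(idx.n_voxels), idx, grid,
                            label=f"noise{i}").zscored() for i in range(4)]
        maps = noise[:2] + planted + noise[2:]
        # slow network TCs for planted, fast for noise (TR = 2 s)
        t = np.arange(200) * 2.0
        rng2 = np.random.default_rng(5)
        slow = [np.sin(2 * np.pi * 0.03 * t + rng2.uniform(0, 6))
                + 0.05 * rng2.standard_normal(t.size) for _ in range(8)]
        fast = [np.sin(2 * np.pi * 0.2 * t + rng2.uniform(0, 6))
                + 0.05 * rng2.standard_normal(t.size) for _ in range(4)]
        tcs = np.vstack(fast[:2] + slow + fast[2:])
        gm = SpatialMap(sum(m.values for m in planted), idx, grid).zscored()
        icns = ReferenceSet(planted)
        report = screen_components(maps, tcs, 2.0, icns, gm=gm)
        picked = set(report.selected_indices())
        assert picked == {2, 3, 4, 5, 6, 7, 8, 9}

    def test_selection_invariant_to_order_and_sign(self):
        cfg = SimulationConfig(grid_dims=(10, 10, 10), n_sources=4, seed=6)
        planted = [m.zscored(label=f"net{i}")
                   for i, (m, _) in enumerate(generate_sources(cfg))]
        idx, grid = planted[0].mask_index, planted[0].grid
        t = np.arange(100) * 2.0
        tcs = np.vstack([np.sin(2 * np.pi * 0.03 * t)] * 4)
        icns = ReferenceSet(planted)
        rep1 = screen_components(planted, tcs, 2.0, icns)
        flipped = [SpatialMap(-m.values, m.mask_index, m.grid, label=m.label)
                   for m in reversed(planted)]
        rep2 = screen_components(flipped, tcs, 2.0, icns)
        matched1 = dict(zip(rep1.table["component"], rep1.table["best_icn"]))
        matched2 = dict(zip(rep2.table["component"], rep2.table["best_icn"]))
        assert matched1 == matched2
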