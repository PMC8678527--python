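"""FNC matrices, group comparison with FDR, alteration counts."""

import numpy as np
import pytest

from rinan.fnc import (FncMatrix, alteration_counts, compute_fnc,
                       group_compare)
from rinan.split import NetworkSplit


def _splits_from_tcs(tcs_act, tcs_ine, labels=None):
    n = len(tcs_act)
    labels = labels or [f"net{i}" for i in range(n)]
    out = []
    for i in range(n):
        out.append(NetworkSplit(labels[i], 10, 20, np.asarray(tcs_act[i]),
                                np.asarray(tcs_ine[i]), False, False))
    return out


def _random_splits(rng, n_nets=8, n_time=120):
    return _splits_from_tcs(rng.standard_normal((n_nets, n_time)),
                            rng.standard_normal((n_nets, n_time)))


class TestComputeFnc:
    def test_eight_networks_all_mode_is_16_by_16(self):
        rng = np.random.default_rng(0)
        fnc = compute_fnc(_random_splits(rng), "all")
        assert fnc.values.shape == (16, 16)
        assert fnc.labels[:4] == ["net0_i", "net0_a", "net1_i", "net1_a"]

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        fnc = compute_fnc(_random_splits(rng), "all")
        assert np.allclose(fnc.values, fnc.values.T)
        assert np.allclose(np.diag(fnc.values), 1.0)
        assert np.nanmax(np.abs(fnc.values)) <= 1.0 + 1e-12

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(2)
        n_time = 5000
        z = rng.standard_normal((2, n_time))
        a = z[0]
        b = 0.8 * z[0] + np.sqrt(1 - 0.64) * z[1]
        splits = _splits_from_tcs([a, b], rng.standard_normal((2, n_time)))
        fnc = compute_fnc(splits, "act")
        assert fnc.values[0, 1] == pytest.approx(0.8, abs=0.03)

    def test_original_mode_uses_supplied_tcs(self):
        rng = np.random.default_rng(3)
        splits = _random_splits(rng, n_nets=3)
        tcs = rng.standard_normal((3, 120))
        fnc = compute_fnc(splits, "original", tcs)
        assert fnc.values.shape == (3, 3)
        assert fnc.values[0, 1] == pytest.approx(
            np.corrcoef(tcs[0], tcs[1])[0, 1])

    def test_original_mode_consistent_with_direct_correlation(self):
        # "original" on full TCs == treating each network unsplit
        rng = np.random.default_rng(4)
        splits = _random_splits(rng, n_nets=4)
        tcs = rng.standard_normal((4, 200))
        fnc = compute_fnc(splits, "original", tcs)
        assert np.allclose(fnc.values, np.corrcoef(tcs))

    def test_empty_side_flagged_missing(self):
        rng = np.random.default_rng(5)
        splits = _random_splits(rng, n_nets=2)
        splits[0].rin_empty = True
        splits[0].t_ine = np.zeros(120)
        fnc = compute_fnc(splits, "all")
        assert fnc.missing[0]  # net0_i row
        assert np.isnan(fnc.values[0, 2])

    def test_constant_tc_recorded_missing_with_warning(self):
        rng = np.random.default_rng(6)
        splits = _random_splits(rng, n_nets=2)
        splits[1].t_act = np.full(120, 2.0)
        with pytest.warns(UserWarning, match="constant"):
            fnc = compute_fnc(splits, "act")
        assert np.isnan(fnc.values[0, 1])


class TestGroupCompare:
    def _cohort(self, rng, n_sub, effect_pair=None, effect_r=0.0,
                n_nets=4, n_time=150):
        out = []
        for _ in range(n_sub):
            z = rng.standard_normal((2 * n_nets, n_time))
            if effect_pair is not None and effect_r != 0:
                i, j = effect_pair
                z[j] = effect_r * z[i] + np.sqrt(1 - effect_r ** 2) * z[j]
            splits = _splits_from_tcs(z[:n_nets], z[n_nets:])
            out.append(compute_fnc(splits, "all"))
        return out

    def test_null_false_positive_fraction_at_most_alpha(self):
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(30):
            A = self._cohort(rng, 10)
            B = self._cohort(rng, 10)
            cmp = group_compare(A, B, alpha=0.05)
            n = len(cmp.labels)
            iu = np.triu_indices(n, k=1)
            fracs.append(cmp.significant[iu].mean())
        assert np.mean(fracs) <= 0.05

    def test_planted_difference_detected_with_positive_direction(self):
        rng = np.random.default_rng(8)
        hits = 0
        reps = 20
        for _ in range(reps):
            A = self._cohort(rng, 15)
            B = self._cohort(rng, 15, effect_pair=(0, 1), effect_r=0.6)
            cmp = group_compare(A, B, alpha=0.05)
            i = cmp.labels.index("net0_a")
            j = cmp.labels.index("net1_a")
            hits += bool(cmp.significant[i, j] and cmp.direction[i, j] > 0)
        assert hits >= 19

    def test_zero_alpha_nothing_significant(self):
        rng = np.random.default_rng(9)
        A = self._cohort(rng, 8)
        B = self._cohort(rng, 8, effect_pair=(0, 1), effect_r=0.8)
        cmp = group_compare(A, B, alpha=0.0)
        assert not cmp.significant.any()

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(10)
        A = self._cohort(rng, 6)
        B = self._cohort(rng, 6)
        c1 = group_compare(A, B)
        c2 = group_compare(A[::-1], B[::-1])
        assert np.allclose(c1.p_values, c2.p_values)

    def test_mismatched_labels_rejected(self):
        rng = np.random.default_rng(11)
        A = self._cohort(rng, 3)
        B = self._cohort(rng, 3)
        B[0].labels[0] = "other"
        with pytest.raises(ValueError, match="label"):
            group_compare(A, B)


class TestBenjaminiHochberg:
    def test_matches_brute_force_step_up(self):
        # exhaustive check of the BH step-up rule on short random p-vectors
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        for trial in range(200):
            m = rng.integers(1, 21)
            p = rng.random(m)
            alpha = rng.choice([0.01, 0.05, 0.1, 0.25])
            rej, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
            order = np.argsort(p)
            thresh = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= alpha * rank / m:
                    thresh = rank
            brute = np.zeros(m, dtype=bool)
            brute[order[:thresh]] = True
            assert np.array_equal(rej, brute)


class TestAlterationCounts:
    def _fake_cmp(self, labels, edges):
        n = len(labels)
        sig = np.zeros((n, n), dtype=bool)
        direc = np.zeros((n, n), dtype=np.int8)
        for i, j, d in edges:
            sig[i, j] = sig[j, i] = True
            direc[i, j] = direc[j, i] = d
        from rinan.fnc import FncComparison

        return FncComparison(labels, np.zeros((n, n)), np.ones((n, n)),
                             np.ones((n, n)), sig, direc, 0.05, n * (n - 1) // 2)

    def test_no_significance_all_zero(self):
        cmp = self._fake_cmp(["a_i", "a_a", "b_i", "b_a"], [])
        counts = alteration_counts(cmp)
        assert (counts[["total", "enhanced", "weakened"]] == 0).all().all()

    def test_single_edge_counted_once_per_endpoint(self):
        cmp = self._fake_cmp(["X_a", "Y_i", "Z_a"], [(0, 1, 1)])
        counts = alteration_counts(cmp).set_index("network")
        assert counts.loc["X_a", "total"] == 1
        assert counts.loc["Y_i", "total"] == 1
        assert counts.loc["Z_a", "total"] == 0

    def test_enhanced_and_weakened_split(self):
        # 3 enhanced + 2 weakened edges touching network 0
        edges = [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, -1), (0, 5, -1)]
        labels = [f"n{i}" for i in range(6)]
        counts = alteration_counts(self._fake_cmp(labels, edges))
        row = counts.set_index("network").loc["n0"]
        assert (row["total"], row["enhanced"], row["weakened"]) == (5, 3, 2)
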