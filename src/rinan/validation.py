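"""End-to-end validation studies on synthetic cohorts.

Each function runs one self-contained study — generation, estimation,
measurement — and returns the scalar quantities a reviewer would check:
the time-course decomposition identity, source recovery by group ICA and by
reference-guided ICA, false-discovery calibration and planted-edge power of
the FNC group comparison, and the classification advantage of RIN-aware
features when group differences live only on RIN-involving edges.

Every study takes an integer seed and is deterministic given it.  Problem
sizes are chosen so the full battery completes in minutes on one CPU; the
methods note documents them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .classify import (StrategyComparison, SvmConfig, features_from_splits,
                       mcnemar_test)
from .fnc import compute_fnc, group_compare
from .gica import GroupICA
from .reference_ica import GigIcaConfig, ReferenceSet, gig_ica_subject
from .simulate import (SimulationConfig, generate_cohort,
                       generate_guided_cohort, make_group_fnc)
from .split import an_size_curve, make_mask, reconstruction_check, \
    split_timecourses


def _sub_seed(seed: int, offset: int) -> int:
    return int((seed * 1000 + offset) % (2 ** 31 - 1))


def decomposition_identity_error(seed: int, n_subjects: int = 20,
                                 mus=(1.0, 2.0, 3.0, 4.0)) -> dict:
    """Worst-case relative error of Va*T_act + Ve*T_ine vs V*T_full.

    Checked for every subject x component x mu on a noisy 8-source cohort,
    together with the AN-size monotonicity over the mu sweep.
    """
    cfg = SimulationConfig(grid_dims=(10, 10, 10), n_time=150, n_sources=8,
                           noise_sd=0.3, n_subjects_per_group=n_subjects // 2,
                           seed=_sub_seed(seed, 1))
    runs, truth = generate_cohort(cfg)
    zmaps = [m.zscored() for m in truth.source_maps]
    worst = 0.0
    monotonicity_violations = 0
    for run in runs:
        for zmap in zmaps:
            for mu in mus:
                split = split_timecourses(run, zmap, make_mask(zmap, mu))
                worst = max(worst, reconstruction_check(run, zmap, split))
    for zmap in zmaps:
        curve = an_size_curve(zmap, mus=mus)
        sizes = [curve[m] for m in mus]
        monotonicity_violations += sum(a < b for a, b in
                                       zip(sizes, sizes[1:]))
    return {"max_relative_error": worst,
            "monotonicity_violations": monotonicity_violations,
            "n": n_subjects * len(zmaps) * len(mus)}


def gica_source_recovery(seed: int) -> dict:
    """Min matched |spatial r| between group ICA maps and the true sources.

    Noiseless 8-source cohort: 10 subjects, 150 time points, 10x10x10 grid;
    group decomposition with 20 ICASSO restarts.
    """
    from scipy.optimize import linear_sum_assignment

    cfg = SimulationConfig(grid_dims=(10, 10, 10), n_time=150, n_sources=8,
                           noise_sd=0.0, n_subjects_per_group=5,
                           seed=_sub_seed(seed, 2))
    runs, truth = generate_cohort(cfg)
    res = GroupICA(runs, n_components=8, icasso_repeats=20).fit(
        seed=_sub_seed(seed, 3))
    M = np.vstack([m.values for m in res.group_maps])
    T = np.vstack([m.zscored().values for m in truth.source_maps])
    cc = np.abs(np.corrcoef(np.vstack([M, T]))[:8, 8:])
    r, c = linear_sum_assignment(-cc)
    matched = cc[r, c]
    return {"min_matched_abs_r": float(matched.min()),
            "mean_matched_abs_r": float(matched.mean()),
            "min_stability": float(res.stability_index.min()), "n": 8}


def guided_recovery(seed: int, n_subjects: int = 10) -> dict:
    """Reference-guided estimation vs per-subject truth.

    Subject maps are perturbed from the group references at spatial r = 0.8;
    scores are the mean matched correlation to the subject truth and the
    fraction of components recovered closer to the truth than to the
    reference they started from (noise_sd = 0.2).
    """
    cfg = SimulationConfig(grid_dims=(10, 10, 10), n_time=150, n_sources=8,
                           noise_sd=0.2, n_subjects_per_group=n_subjects // 2,
                           seed=_sub_seed(seed, 4))
    gc = generate_guided_cohort(cfg, reference_r=0.8)
    refs = ReferenceSet(gc.references)
    r_truth_all, closer = [], 0
    total = 0
    for s, run in enumerate(gc.runs):
        res = gig_ica_subject(run, refs, GigIcaConfig())
        for i, m in enumerate(res.maps):
            r_truth = np.corrcoef(m.values, gc.subject_maps[s][i].values)[0, 1]
            r_ref = np.corrcoef(m.values, gc.references[i].values)[0, 1]
            r_truth_all.append(r_truth)
            closer += r_truth >= r_ref
            total += 1
    return {"mean_r_to_subject_truth": float(np.mean(r_truth_all)),
            "fraction_closer_to_truth": closer / total, "n": total}


def _cohort_fnc_stack(cfg: SimulationConfig, mu: float = 3.0):
    """All-mode FNC matrices per subject from true-map splits."""
    runs, truth = generate_cohort(cfg)
    zmaps = [m.zscored() for m in truth.source_maps]
    fncs = []
    for run in runs:
        splits = [split_timecourses(run, z, make_mask(z, mu)) for z in zmaps]
        fncs.append(compute_fnc(splits, "all"))
    return fncs, truth


def fdr_null_calibration(seed: int, n_replicates: int = 100,
                         n_per_group: int = 20) -> dict:
    """Mean fraction of FDR-significant FNC elements with no true difference.

    Per replicate a paired cohort with identical group correlation structure
    is generated, split at mu = 3, and compared; with Benjamini-Hochberg
    control at 0.05 the mean significant fraction must stay at or below it.
    """
    base = make_group_fnc(8, paired=True)
    fracs = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(grid_dims=(10, 10, 10), n_time=150,
                               n_sources=8, noise_sd=0.2,
                               group_fnc=(base, base),
                               n_subjects_per_group=n_per_group,
                               seed=_sub_seed(seed, 100 + rep))
        fncs, truth = _cohort_fnc_stack(cfg)
        A = [f for f, g in zip(fncs, truth.group_labels) if g == 0]
        B = [f for f, g in zip(fncs, truth.group_labels) if g == 1]
        cmp = group_compare(A, B, alpha=0.05)
        iu = np.triu_indices(len(cmp.labels), k=1)
        fracs.append(float(cmp.significant[iu].mean()))
    return {"mean_significant_fraction": float(np.mean(fracs)),
            "n": n_replicates}


def planted_edge_power(seed: int, n_replicates: int = 50,
                       n_per_group: int = 30, effect_r: float = 0.6) -> dict:
    """Detection rate of one planted AN-RIN edge difference (0.6 vs 0.0).

    The edge couples source 0's core (AN) to source 1's halo (RIN) in group
    1 only; a hit requires the corresponding FNC element to be FDR-
    significant with positive direction (group 1 stronger).
    """
    base = make_group_fnc(8, paired=True)
    planted = make_group_fnc(8, paired=True, edges=[(0, 8 + 1, effect_r)])
    hits = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(grid_dims=(10, 10, 10), n_time=150,
                               n_sources=8, noise_sd=0.2,
                               group_fnc=(base, planted),
                               n_subjects_per_group=n_per_group,
                               seed=_sub_seed(seed, 300 + rep))
        fncs, truth = _cohort_fnc_stack(cfg)
        A = [f for f, g in zip(fncs, truth.group_labels) if g == 0]
        B = [f for f, g in zip(fncs, truth.group_labels) if g == 1]
        cmp = group_compare(A, B, alpha=0.05)
        i = cmp.labels.index("source0_a")
        j = cmp.labels.index("source1_i")
        hits += bool(cmp.significant[i, j] and cmp.direction[i, j] > 0)
    return {"detection_rate": hits / n_replicates, "n": n_replicates}


def rin_feature_advantage(seed: int, n_repeats: int = 100,
                          n_per_group: int = 30) -> dict:
    """Classification gain of RIN-aware features over the original FNC.

    Group differences are planted only on RIN-involving (halo) edges; the
    full pipeline (group ICA -> guided subject ICA -> subject-z splitting ->
    FNC features) is run once, then each strategy is evaluated over
    ``n_repeats`` stratified 70/30 splits.  Returns mean accuracies, the
    AllFNC-vs-Original and InertFNC-vs-Original t-test p-values, and the
    AllFNC-vs-Original McNemar p on the first split.
    """
    from .pipeline import RunConfig, SimulateSection, run_pipeline

    cfg = RunConfig(
        seed=_sub_seed(seed, 5), classify_repeats=n_repeats,
        simulate=SimulateSection(
            grid_dims=(10, 10, 10), n_subjects_per_group=n_per_group,
            noise_sd=0.2,
            planted_edges=[(8 + 0, 8 + 1, 0.6), (8 + 2, 8 + 3, 0.6)]))
    res = run_pipeline(cfg)
    cls = res.classification
    acc = {name: float(cls.metric(name).mean()) for name in cls.results}
    _, p_all = cls.compare("AllFNC", "OriginalFNC")
    _, p_inert = cls.compare("InertFNC", "OriginalFNC")
    # McNemar on one common test split
    r_all = cls.results["AllFNC"][0]
    r_orig = cls.results["OriginalFNC"][0]
    _, p_mcnemar = mcnemar_test(r_all.predictions, r_orig.predictions,
                                r_all.truth)
    fnc_side = res.fnc_by_mode["all"][0].side
    return {"accuracy": acc,
            "p_allfnc_vs_original": float(p_all),
            "p_inertfnc_vs_original": float(p_inert),
            "p_mcnemar_allfnc_vs_original": float(p_mcnemar),
            "allfnc_matrix_side": int(fnc_side),
            "n": n_repeats}


def mcnemar_closed_form() -> dict:
    """The hand-checkable discordant-pair statistic: b=1, c=9 -> 4.9."""
    truth = np.ones(10, dtype=int)
    predA = np.array([1] + [0] * 9)
    predB = np.array([0] + [1] * 9)
    stat, p = mcnemar_test(predA, predB, truth)
    return {"statistic": float(stat), "p": float(p), "n": 10}
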