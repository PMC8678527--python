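"""Activation-network / relatively-inert-network splitting.

Every network (independent component) is partitioned by a threshold ``mu``
applied to a statistic map: voxels whose statistic strictly exceeds ``mu``
form the activation network (AN), the remaining in-mask voxels the
relatively inert network (RIN).  The two sub-network time courses are the
z-score-weighted voxel means over each side,

    T_act = (1/Va) sum_v y_v d_v f_v,
    T_ine = (1/Ve) sum_v y_v (1 - d_v) f_v,

with ``d`` the activation indicator and ``Va + Ve = V`` the voxel counts, so
``Va T_act + Ve T_ine`` always reconstructs ``V`` times the full-network
time course — the decomposition identity checked throughout the test suite.

The statistic thresholded is either each subject's own component z-map
(``subject_z`` — label-free, usable on new subjects) or the group one-sample
t-map across subjects (``group_t`` — one mask per group, used for the group
difference analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import BoldRun, SpatialMap
from .reference_ica import compute_tc

#: replacement for infinite t at zero-variance voxels
T_CAP = 1e6


@dataclass
class ActivationMask:
    """Binary activation indicator for one network at threshold ``mu``."""

    d: np.ndarray
    mu: float
    source_statistic: str = "subject_z"   # or "group_t"

    def __post_init__(self):
        self.d = np.asarray(self.d).astype(np.int8)
        if not np.isin(self.d, (0, 1)).all():
            raise ValueError("activation indicator must be 0/1")

    @property
    def an_count(self) -> int:
        return int(self.d.sum())

    @property
    def rin_count(self) -> int:
        return int(self.d.size - self.d.sum())


@dataclass
class NetworkSplit:
    """AN/RIN voxel counts and time courses for one network of one subject."""

    label: str
    an_count: int
    rin_count: int
    t_act: np.ndarray
    t_ine: np.ndarray
    an_empty: bool
    rin_empty: bool

    @property
    def labels(self) -> tuple[str, str]:
        """Column labels following the ``_a`` / ``_i`` suffix convention."""
        return f"{self.label}_a", f"{self.label}_i"


def group_activation_tmap(subject_maps: list[SpatialMap],
                          label: str = "") -> SpatialMap:
    """Voxelwise one-sample t statistic of subject map values against 0.

    Zero across-subject variance yields ``t = sign(mean) * 1e6`` (0 when the
    mean is also 0), with a warning.
    """
    if len(subject_maps) < 2:
        raise ValueError("need at least 2 subjects for a t-map")
    M = np.vstack([m.values for m in subject_maps])
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    flat = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(M.shape[0]))
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance voxels; t capped")
        t[flat] = np.sign(mean[flat]) * T_CAP
    t = np.clip(t, -T_CAP, T_CAP)
    ref = subject_maps[0]
    return SpatialMap(t, ref.mask_index, ref.grid, label=label or "group_t")


def make_mask(stat_map: SpatialMap, mu: float = 3.0,
              source_statistic: str = "subject_z") -> ActivationMask:
    """Threshold a statistic map: AN voxels are those strictly above ``mu``.

    Values exactly equal to ``mu`` fall in the RIN.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    return ActivationMask((stat_map.values > mu).astype(np.int8), float(mu),
                          source_statistic)


def split_timecourses(run: BoldRun, spatial_map: SpatialMap,
                      mask: ActivationMask) -> NetworkSplit:
    """Split a network's time course into its AN and RIN parts.

    An empty side (no AN or no RIN voxels) gets a zero time course and an
    explicit emptiness flag; downstream connectivity code treats flagged
    sides as missing rather than zero.
    """
    y = spatial_map.values
    if y.size != run.n_voxels or mask.d.size != y.size:
        raise ValueError("length mismatch between run, map, and mask")
    d = mask.d.astype(float)
    va = int(d.sum())
    ve = y.size - va
    wa = y * d
    wi = y * (1.0 - d)
    t_act = run.data @ wa / va if va > 0 else np.zeros(run.n_time)
    t_ine = run.data @ wi / ve if ve > 0 else np.zeros(run.n_time)
    return NetworkSplit(spatial_map.label, va, ve, t_act, t_ine,
                        an_empty=va == 0, rin_empty=ve == 0)


def split_network(run: BoldRun, spatial_map: SpatialMap, mu: float = 3.0,
                  stat_map: SpatialMap | None = None,
                  source_statistic: str = "subject_z") -> NetworkSplit:
    """Convenience: threshold (the subject z-map by default) and split."""
    stat = stat_map if stat_map is not None else spatial_map
    return split_timecourses(run, spatial_map,
                             make_mask(stat, mu, source_statistic))


def reconstruction_check(run: BoldRun, spatial_map: SpatialMap,
                         split: NetworkSplit) -> float:
    """Max relative deviation of ``Va T_act + Ve T_ine`` from ``V T_full``."""
    full = compute_tc(run, spatial_map) * spatial_map.n_voxels
    combined = split.an_count * split.t_act + split.rin_count * split.t_ine
    scale = max(np.abs(full).max(), 1e-30)
    return float(np.abs(combined - full).max() / scale)


def difference_map(groupA_mask: ActivationMask, groupB_mask: ActivationMask,
                   groupA_maps: list[SpatialMap],
                   groupB_maps: list[SpatialMap],
                   alpha: float = 0.05,
                   equal_var: bool = False) -> SpatialMap:
    """Signed hot/cold map of activation-status differences between groups.

    Voxels are labelled +1 (*hot*: group A activated, group B inert),
    -1 (*cold*: group A inert, group B activated), 0 otherwise; a nonzero
    label additionally requires the voxelwise two-sample t-test on the raw
    subject map values to reach ``p < alpha``.  Hot and cold sets are
    disjoint by construction.
    """
    if len(groupA_maps) < 2 or len(groupB_maps) < 2:
        raise ValueError("need at least 2 subjects per group")
    A = np.vstack([m.values for m in groupA_maps])
    B = np.vstack([m.values for m in groupB_maps])
    if A.shape[1] != B.shape[1]:
        raise ValueError("group masks / maps are on different grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    p = np.where(np.isfinite(p), p, 1.0)
    sig = p < alpha
    dA = groupA_mask.d.astype(bool)
    dB = groupB_mask.d.astype(bool)
    label = np.zeros(A.shape[1], dtype=np.int8)
    label[dA & ~dB & sig] = 1     # hot: A-AN intersect B-RIN
    label[~dA & dB & sig] = -1    # cold: A-RIN intersect B-AN
    ref = groupA_maps[0]
    return SpatialMap(label, ref.mask_index, ref.grid, label="difference")


def an_size_curve(stat_map: SpatialMap,
                  mus=(1.0, 2.0, 3.0, 4.0)) -> dict[float, int]:
    """AN voxel count as a function of mu (non-increasing by construction)."""
    return {float(mu): make_mask(stat_map, mu).an_count for mu in mus}
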