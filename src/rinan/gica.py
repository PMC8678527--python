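"""Group spatial ICA: two-stage PCA, Infomax, MDL order selection, ICASSO.

The group decomposition follows the temporal-concatenation recipe standard in
resting-state fMRI: each subject's time dimension is reduced by PCA, the
reduced data are stacked along the (reduced) time axis, a second PCA brings
the stack down to the requested component count, and Infomax ICA extracts
spatially independent group maps.  Model order can be estimated from the
eigenvalues of the temporal covariance with the minimum-description-length
(MDL) criterion, and stability is assessed ICASSO-style by re-running ICA
from many random starts and clustering the pooled components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kurtosis as _kurtosis

from .containers import BoldRun, MaskIndex, SpatialMap, VolumeGrid


# ---------------------------------------------------------------------------
# model order
# ---------------------------------------------------------------------------

def _temporal_eigenvalues(data: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the time-by-time covariance (voxels = samples)."""
    X = data - data.mean(axis=1, keepdims=True)
    C = (X @ X.T) / X.shape[1]
    w = np.linalg.eigvalsh(C)[::-1]
    return np.clip(w, 0.0, None)


def estimate_order_mdl(run: BoldRun | np.ndarray) -> int:
    """Estimate the number of signal components by the MDL criterion.

    Uses the classical eigenvalue form: for candidate order ``k`` the code
    length is ``-N (p-k) log(g_k / a_k) + 0.5 k (2p - k) log N`` where
    ``g_k`` / ``a_k`` are the geometric / arithmetic means of the trailing
    ``p-k`` eigenvalues and ``N`` the number of voxel samples; the minimiser
    over ``k`` is returned.  The criterion depends only on eigenvalue ratios,
    so it is invariant to a global rescaling of the data.  Candidates are
    capped at the numerical rank.
    """
    data = run.data if isinstance(run, BoldRun) else np.asarray(run)
    p, N = data.shape
    if p <= 2:
        raise ValueError("need more than 2 time points for order estimation")
    w = _temporal_eigenvalues(data)
    rank = int(np.sum(w > w[0] * 1e-10))
    w = np.maximum(w, w[0] * 1e-12)
    logw = np.log(w)
    # trailing sums for arithmetic/geometric means
    tail_sum = np.cumsum(w[::-1])[::-1]
    tail_logsum = np.cumsum(logw[::-1])[::-1]
    ks = np.arange(0, min(rank, p - 1))
    m = p - ks
    log_a = np.log(tail_sum[ks] / m)
    log_g = tail_logsum[ks] / m
    mdl = -N * m * (log_g - log_a) + 0.5 * ks * (2 * p - ks) * np.log(N)
    return int(ks[np.argmin(mdl)])


# ---------------------------------------------------------------------------
# two-stage PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class ReductionResult:
    """PCA reduction of one data block (rows uncorrelated, variance order)."""

    reduced: np.ndarray       # k x n_voxels
    projection: np.ndarray    # k x n_time transform that was applied
    eigenvalues: np.ndarray   # descending, length k


def _pca_reduce(data: np.ndarray, k: int) -> ReductionResult:
    X = data - data.mean(axis=1, keepdims=True)
    C = (X @ X.T) / X.shape[1]
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:k]
    proj = V[:, order].T
    return ReductionResult(proj @ X, proj, np.clip(w[order], 0.0, None))


def reduce_and_concat(runs: list[BoldRun], subject_k: int, group_k: int):
    """Per-subject PCA, temporal concatenation, then group-level PCA.

    Returns ``(group_reduced, subject_results, group_result)`` where
    ``group_reduced`` is the ``group_k x n_voxels`` matrix (identical to
    ``group_result.reduced``); all projections are retained so subject data
    can be back-projected.
    """
    if not runs:
        raise ValueError("no runs supplied")
    mask0 = runs[0].mask_index
    for r in runs[1:]:
        if r.mask_index != mask0:
            raise ValueError("all runs must share the same mask")
    if subject_k > runs[0].n_time:
        raise ValueError("subject_k exceeds the number of time points")
    if group_k > subject_k * len(runs):
        raise ValueError("group_k exceeds the stacked reduced dimension")
    subject_results = [_pca_reduce(r.data, subject_k) for r in runs]
    stacked = np.vstack([s.reduced for s in subject_results])
    group_result = _pca_reduce(stacked, group_k)
    return group_result.reduced, subject_results, group_result


def whiten_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale/rotate rows to zero mean, identity covariance.

    Returns ``(whitened, sphering)`` with ``whitened = sphering @ centred``.
    """
    X = data - data.mean(axis=1, keepdims=True)
    C = (X @ X.T) / X.shape[1]
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-12, None)
    sphering = (V / np.sqrt(w)) @ V.T
    return sphering @ X, sphering


# ---------------------------------------------------------------------------
# Infomax ICA
# ---------------------------------------------------------------------------

def infomax_ica(whitened: np.ndarray, seed: int = 0, max_iter: int = 500,
                tol: float = 1e-7, learning_rate: float = 0.3,
                extended: bool = True):
    """Natural-gradient Infomax ICA on whitened data.

    The update is the extended form ``W <- W + lr (I - K tanh(u) u^T/V
    - u u^T/V) W`` where ``K`` holds the estimated kurtosis sign of each
    component (+1 super-Gaussian, i.e. the classic logistic nonlinearity,
    -1 sub-Gaussian); with ``extended=False`` all signs are fixed at +1.
    The learning rate is halved whenever the weight change oscillates or the
    weights leave the finite range, restarting from the last good iterate.

    Returns ``(W, components, converged)``; component rows are scaled to
    unit variance (and W rescaled to match).
    """
    X = np.asarray(whitened, dtype=float)
    k, V = X.shape
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((k, k)))
    W = q
    I = np.eye(k)
    lr = learning_rate
    converged = False
    prev_change = np.inf
    for _ in range(max_iter):
        u = W @ X
        if extended:
            signs = np.sign(
                np.mean(1.0 / np.cosh(u) ** 2, axis=1) * np.mean(u ** 2, axis=1)
                - np.mean(u * np.tanh(u), axis=1))
            signs[signs == 0] = 1.0
        else:
            signs = np.ones(k)
        grad = (I - (signs[:, None] * np.tanh(u)) @ u.T / V - (u @ u.T) / V) @ W
        W_new = W + lr * grad
        if not np.all(np.isfinite(W_new)) or np.abs(W_new).max() > 1e8:
            lr *= 0.5
            if lr < 1e-6:
                raise RuntimeError("Infomax diverged even at minimal learning rate")
            continue
        change = np.linalg.norm(W_new - W) / max(np.linalg.norm(W), 1e-12)
        if change > prev_change * 1.5:
            lr *= 0.9
        prev_change = change
        W = W_new
        if change < tol:
            converged = True
            break
    comps = W @ X
    sd = comps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    comps = comps / sd
    W = W / sd
    # orient: positive skew (activation blobs point upward)
    flip = np.where(np.mean(comps ** 3, axis=1) < 0, -1.0, 1.0)
    return W * flip[:, None], comps * flip[:, None], converged


# ---------------------------------------------------------------------------
# ICASSO stability selection
# ---------------------------------------------------------------------------

@dataclass
class GroupICAResult:
    """Group decomposition output (maps z-scored over in-mask voxels)."""

    maps: np.ndarray                  # n_components x n_voxels, z-scored
    unmixing: np.ndarray              # n_components x k (centrotype rows)
    group_mixing: np.ndarray          # k x n_components least-squares mixing
    n_components: int
    stability_index: np.ndarray       # per component, in [0, 1]
    converged: bool
    group_maps: list[SpatialMap] = field(default_factory=list)

    def spatial_maps(self, mask_index: MaskIndex, grid: VolumeGrid,
                     labels: list[str] | None = None) -> list[SpatialMap]:
        labels = labels or [f"IC{i + 1}" for i in range(self.n_components)]
        self.group_maps = [SpatialMap(m, mask_index, grid, label=l)
                           for m, l in zip(self.maps, labels)]
        return self.group_maps


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return M / sd


def icasso_select(whitened: np.ndarray, n_components: int, repeats: int = 20,
                  seed: int = 0) -> GroupICAResult:
    """Repeat Infomax from random starts and keep each cluster's centrotype.

    The pooled components of all runs are clustered by average-linkage
    agglomeration on ``1 - |spatial correlation|`` into ``n_components``
    clusters; each cluster is represented by the member with the highest
    mean within-cluster similarity, and its stability index is the mean
    intra-cluster minus mean extra-cluster similarity.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if n_components != whitened.shape[0]:
        raise ValueError("whitened row count must equal n_components")
    all_comps, all_w, flags = [], [], []
    for r in range(repeats):
        W, comps, ok = infomax_ica(whitened, seed=seed + r)
        all_comps.append(comps)
        all_w.append(W)
        flags.append(ok)
    pooled = np.vstack(all_comps)
    pooled_w = np.vstack(all_w)
    if repeats == 1:
        maps = _zscore_rows(pooled)
        mixing = np.linalg.lstsq(maps.T, whitened.T, rcond=None)[0].T
        return GroupICAResult(maps, pooled_w, mixing, n_components,
                              np.ones(n_components), all(flags))
    sim = np.abs(np.corrcoef(pooled))
    np.fill_diagonal(sim, 1.0)
    Z = linkage(squareform(1.0 - sim, checks=False), method="average")
    assign = fcluster(Z, t=n_components, criterion="maxclust")
    centro_rows, stab = [], []
    for c in range(1, n_components + 1):
        members = np.flatnonzero(assign == c)
        others = np.flatnonzero(assign != c)
        sub = sim[np.ix_(members, members)]
        if len(members) == 1:
            intra = 1.0
            centro_rows.append(members[0])
        else:
            mean_in = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
            centro_rows.append(members[np.argmax(mean_in)])
            intra = mean_in.mean()
        extra = sim[np.ix_(members, others)].mean() if len(others) else 0.0
        stab.append(intra - extra)
    order = np.argsort(centro_rows)  # stable, arbitrary component order
    centro_rows = np.asarray(centro_rows)[order]
    maps = _zscore_rows(pooled[centro_rows])
    mixing = np.linalg.lstsq(maps.T, whitened.T, rcond=None)[0].T
    return GroupICAResult(maps, pooled_w[centro_rows], mixing, n_components,
                          np.asarray(stab)[order], all(flags))


# ---------------------------------------------------------------------------
# model front-end
# ---------------------------------------------------------------------------

class GroupICA:
    """Group ICA model over a list of subject runs.

    Parameters
    ----------
    runs : list of BoldRun
        Subject data sharing one mask.
    n_components : int, optional
        Group model order; estimated per run by MDL (median across subjects)
        when omitted.
    subject_k : int, optional
        Per-subject PCA retention; default ``ceil(1.5 * n_components)``
        capped at ``n_time``.
    icasso_repeats : int
        Number of Infomax restarts pooled for stability selection.
    """

    def __init__(self, runs: list[BoldRun], n_components: int | None = None,
                 subject_k: int | None = None, icasso_repeats: int = 20):
        self.runs = runs
        self.n_components = n_components
        self.subject_k = subject_k
        self.icasso_repeats = icasso_repeats

    def fit(self, seed: int = 0) -> "GroupICAResults":
        from .io import center_and_scale

        runs = [center_and_scale(r, "voxel_mean") for r in self.runs]
        k = self.n_components
        if k is None:
            orders = [estimate_order_mdl(r) for r in runs]
            k = max(int(np.median(orders)), 2)
        sk = self.subject_k or min(int(np.ceil(1.5 * k)), runs[0].n_time)
        sk = max(sk, k)
        group_reduced, subj_res, group_res = reduce_and_concat(runs, sk, k)
        whitened, sphering = whiten_rows(group_reduced)
        sel = icasso_select(whitened, k, repeats=self.icasso_repeats, seed=seed)
        maps = sel.spatial_maps(runs[0].mask_index, runs[0].grid)
        return GroupICAResults(self, sel, maps, subj_res, group_res, seed)


class GroupICAResults:
    """Fitted group decomposition: z-scored maps plus stability diagnostics."""

    def __init__(self, model, selection: GroupICAResult,
                 maps: list[SpatialMap], subject_reductions, group_reduction,
                 seed: int):
        self.model = model
        self.selection = selection
        self.group_maps = maps
        self.subject_reductions = subject_reductions
        self.group_reduction = group_reduction
        self.stability_index = selection.stability_index
        self.n_components = selection.n_components
        self.seed = seed

    def summary(self) -> pd.DataFrame:
        rows = []
        for m, s in zip(self.group_maps, self.stability_index):
            kurt = _kurtosis(m.values)
            rows.append({"component": m.label, "stability": s,
                         "kurtosis": kurt,
                         "peak_value": float(m.values.max())})
        return pd.DataFrame(rows)
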