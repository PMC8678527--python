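"""Reference-guided single-subject ICA.

Each subject component is estimated one-at-a-time by maximising a weighted
combination of two objectives over a unit-norm unmixing vector ``w``:

* non-Gaussianity of ``Y = w^T X~`` (``X~`` the subject data whitened to the
  reference count), measured by the negentropy proxy
  ``Q(w) = (E[G(Y)] - E[G(z)])^2`` with a non-quadratic contrast ``G`` and
  ``z`` standard normal — squashed to ``K(w) = (2/pi) arctan(Q)`` so both
  objectives live on comparable scales;
* closeness to a group reference map ``R`` (zero mean, unit variance),
  ``C(w) = E[Y R]`` — the Pearson correlation under the preconditions.

The scalarised objective ``F(w) = a K(w) + (1 - a) C(w)`` (``0 < a < 1``) is
ascended by projected gradient with backtracking, starting from the
reference's projection onto the whitened data.  Applied with externally
supplied references and no group decomposition this is constrained ICA
(cICA) for independent test subjects — the code path is identical.

The component time course is the z-score-weighted voxel mean of the BOLD
series: ``T = (1/V) sum_v y_v f_v`` (:func:`compute_tc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .containers import BoldRun, SpatialMap
from .gica import _pca_reduce


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _gaussian_expectation(contrast: str) -> float:
    """E[G(z)] for z ~ N(0,1), by adaptive quadrature."""
    G = _CONTRASTS[contrast][0]
    val, _ = quad(lambda z: G(z) * np.exp(-z * z / 2) / np.sqrt(2 * np.pi),
                  -12, 12, limit=200)
    return val


_CONTRASTS = {
    # name -> (G, g = G')
    "logcosh": (lambda y: np.logaddexp(y, -y) - np.log(2.0), np.tanh),
    "kurtosis": (lambda y: y ** 4, lambda y: 4.0 * y ** 3),
}


def negentropy_proxy(y: np.ndarray, contrast: str = "logcosh") -> float:
    """``(E[G(y)] - E[G(z)])^2`` for a zero-mean unit-variance sample ``y``."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    G = _CONTRASTS[contrast][0]
    return float((G(y).mean() - _gaussian_expectation(contrast)) ** 2)


def closeness(y: np.ndarray, r: np.ndarray) -> float:
    """``E[y r]``: Pearson correlation for zero-mean unit-variance inputs."""
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    if y.shape != r.shape:
        raise ValueError("length mismatch")
    return float(np.mean(y * r))


def compute_tc(run: BoldRun, spatial_map: SpatialMap) -> np.ndarray:
    """Component time course: mean BOLD series weighted by the map z-scores.

    ``T(t) = (1/V) sum_v y_v f_v(t)`` over all in-mask voxels.
    """
    y = spatial_map.values
    if y.size != run.n_voxels:
        raise ValueError("map / run voxel count mismatch")
    return run.data @ y / y.size


# ---------------------------------------------------------------------------
# the optimiser
# ---------------------------------------------------------------------------

@dataclass
class GigIcaConfig:
    """Optimiser settings; ``a`` trades non-Gaussianity (1) vs closeness (0)."""

    a: float = 0.5
    contrast: str = "logcosh"
    learning_rate: float = 1.0
    tol: float = 1e-9
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.a < 1):
            raise ValueError("a must lie strictly in (0, 1)")
        if self.contrast not in _CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass
class ReferenceSet:
    """Group reference maps, each scaled to zero mean and unit variance."""

    references: list[SpatialMap]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.references = [r.zscored(label=r.label) for r in self.references]
        if not self.labels:
            self.labels = [r.label or f"ref{i + 1}"
                           for i, r in enumerate(self.references)]

    def __len__(self):
        return len(self.references)


@dataclass
class SubjectICResult:
    """Per-subject component estimates from the guided optimisation."""

    maps: list[SpatialMap]            # z-scored Y_i
    unmixing_vectors: np.ndarray      # n_components x k, each row unit norm
    time_courses: np.ndarray          # n_components x n_time
    objective_trace: list[np.ndarray]
    converged: list[bool]
    closeness_to_ref: np.ndarray
    duplicate_pairs: list[tuple[int, int]]
    subject_id: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": [m.label for m in self.maps],
            "iterations": [len(t) for t in self.objective_trace],
            "final_objective": [t[-1] for t in self.objective_trace],
            "closeness": self.closeness_to_ref,
            "converged": self.converged,
        })


def _objective_parts(w, Xw, r_values, config):
    G, g = _CONTRASTS[config.contrast]
    y = w @ Xw
    EG = G(y).mean()
    diff = EG - _gaussian_expectation(config.contrast)
    Q = diff * diff
    K = (2.0 / np.pi) * np.arctan(Q)
    C = float(np.mean(y * r_values))
    F = config.a * K + (1 - config.a) * C
    return y, diff, Q, K, C, F


def _gradient(w, Xw, y, diff, Q, r_values, config):
    _, g = _CONTRASTS[config.contrast]
    V = Xw.shape[1]
    dQ = 2.0 * diff * (Xw @ g(y)) / V
    dK = (2.0 / np.pi) / (1.0 + Q * Q) * dQ
    dC = (Xw @ r_values) / V
    return config.a * dK + (1 - config.a) * dC


def whiten_run(run: BoldRun, k: int):
    """Whiten a run to ``k`` rows (zero mean, identity covariance over voxels)."""
    red = _pca_reduce(run.data, k)
    scale = 1.0 / np.sqrt(np.maximum(red.eigenvalues, 1e-12))
    return scale[:, None] * red.reduced, scale[:, None] * red.projection


def gig_ica_subject(run: BoldRun, refs: ReferenceSet,
                    config: GigIcaConfig | None = None) -> SubjectICResult:
    """Estimate one subject's components guided by group references.

    Each reference is optimised independently (no deflation between
    components, faithful to the per-component objective); convergent
    duplicates — two components landing on the same source — are detected
    by pairwise ``|r| > 0.95`` and reported, not removed.
    """
    config = config or GigIcaConfig()
    if len(refs) == 0:
        raise ValueError("reference set is empty")
    k = len(refs)
    Xw, _ = whiten_run(run, k)
    maps, wvecs, traces, conv, clos = [], [], [], [], []
    for i, ref in enumerate(refs.references):
        r_values = ref.values
        if np.allclose(r_values, 0):
            raise ValueError(f"reference {i} is all zero")
        w = Xw @ r_values
        nrm = np.linalg.norm(w)
        if nrm < 1e-12:
            raise ValueError(f"reference {i} has no projection onto the data")
        w = w / nrm
        y, diff, Q, K, C, F = _objective_parts(w, Xw, r_values, config)
        trace = [F]
        lr = config.learning_rate
        ok = False
        for _ in range(config.max_iter):
            grad = _gradient(w, Xw, y, diff, Q, r_values, config)
            accepted = False
            while lr > 1e-10:
                w_new = w + lr * grad
                w_new = w_new / np.linalg.norm(w_new)
                parts = _objective_parts(w_new, Xw, r_values, config)
                if parts[5] >= F:
                    accepted = True
                    break
                lr *= 0.5
            if not accepted:
                break
            w = w_new
            y, diff, Q, K, C, F_new = parts
            trace.append(F_new)
            if abs(F_new - F) < config.tol:
                F = F_new
                ok = True
                break
            F = F_new
            lr *= 1.2  # cautious re-growth after backtracking
        # orient toward the reference
        if np.mean(y * r_values) < 0:
            w, y = -w, -y
        ym = (y - y.mean())
        sd = ym.std()
        if sd > 0:
            ym = ym / sd
        label = refs.labels[i]
        maps.append(SpatialMap(ym, run.mask_index, run.grid, label=label))
        wvecs.append(w)
        traces.append(np.asarray(trace))
        conv.append(ok)
        clos.append(float(np.mean(ym * r_values)))
    tcs = np.vstack([compute_tc(run, m) for m in maps])
    dup = []
    M = np.vstack([m.values for m in maps])
    cc = np.corrcoef(M)
    for i in range(k):
        for j in range(i + 1, k):
            if abs(cc[i, j]) > 0.95:
                dup.append((i, j))
    return SubjectICResult(maps, np.vstack(wvecs), tcs, traces, conv,
                           np.asarray(clos), dup, subject_id=run.subject_id)


# cICA for independent test subjects: externally supplied references, no
# group decomposition — deliberately the very same code path.
cica_subject = gig_ica_subject


class ReferenceICA:
    """Model front-end: guided subject decomposition for one or many runs."""

    def __init__(self, runs: BoldRun | list[BoldRun], references: ReferenceSet,
                 config: GigIcaConfig | None = None):
        self.runs = [runs] if isinstance(runs, BoldRun) else list(runs)
        self.references = references
        self.config = config or GigIcaConfig()

    def fit(self) -> "ReferenceICAResults":
        results = [gig_ica_subject(r, self.references, self.config)
                   for r in self.runs]
        return ReferenceICAResults(self, results)


class ReferenceICAResults:
    """Per-subject guided-ICA results with a cohort-level summary."""

    def __init__(self, model: ReferenceICA, subjects: list[SubjectICResult]):
        self.model = model
        self.subjects = subjects

    def __len__(self):
        return len(self.subjects)

    def __getitem__(self, i) -> SubjectICResult:
        return self.subjects[i]

    def summary(self) -> pd.DataFrame:
        frames = []
        for res in self.subjects:
            df = res.summary()
            df.insert(0, "subject", res.subject_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)
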