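"""Synthetic multi-subject fMRI cohorts with known network structure.

The generator follows the linear mixing model ``X = A S``: each of
``n_sources`` spatial sources is a spherical blob with a high-amplitude inner
*core* (the true activation network, AN) surrounded by a weaker *halo* (the
relatively inert network, RIN); per-subject time courses are Gaussian with a
prescribed group-level correlation matrix, so every downstream stage —
decomposition, AN/RIN splitting, connectivity statistics, classification —
has an exact oracle.

Two time-course layouts are supported, chosen by the side of ``group_fnc``:

* side ``n_sources`` (*unpaired*): one time course drives the whole blob —
  core and halo fluctuate together, as in a single ICA source;
* side ``2 * n_sources`` (*paired*): core and halo carry separate, typically
  highly coupled time courses (ordering: cores ``0..n-1`` then halos
  ``n..2n-1``).  This is the layout that lets group differences be planted
  selectively on halo-involving (RIN) connectivity edges.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .containers import BoldRun, MaskIndex, SpatialMap, VolumeGrid


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def make_group_fnc(n_sources: int, paired: bool = False, coupling: float = 0.6,
                   edges: list[tuple[int, int, float]] | None = None) -> np.ndarray:
    """Build a valid target correlation matrix for the generator.

    Parameters
    ----------
    paired : bool
        If True the matrix has side ``2 * n_sources`` (cores then halos) and
        every core i is correlated with its own halo at ``coupling``.
    edges : list of (i, j, r)
        Extra off-diagonal correlations to plant, indices into the full
        matrix (use ``i`` for core i and ``n_sources + i`` for halo i in
        paired mode).

    Raises
    ------
    ConfigurationError
        If the resulting matrix is not positive semidefinite.
    """
    side = 2 * n_sources if paired else n_sources
    C = np.eye(side)
    if paired:
        for i in range(n_sources):
            C[i, n_sources + i] = C[n_sources + i, i] = coupling
    for i, j, r in edges or []:
        C[i, j] = C[j, i] = r
    _validate_corr(C)
    return C


def _validate_corr(C: np.ndarray) -> None:
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ConfigurationError("group_fnc must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ConfigurationError("group_fnc must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ConfigurationError("group_fnc must have unit diagonal")
    if np.linalg.eigvalsh(C).min() < -1e-8:
        raise ConfigurationError("group_fnc must be positive semidefinite")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Amplitudes are in arbitrary BOLD units; ``noise_sd`` is the standard
    deviation of the additive i.i.d. Gaussian scanner noise on the same
    scale.  ``ar_coeff > 0`` passes every time course through an order-1
    autoregressive filter (then restandardises), giving BOLD-like temporal
    smoothness without changing zero-lag cross-correlations.
    """

    grid_dims: tuple[int, int, int] = (10, 10, 10)
    n_time: int = 150
    n_sources: int = 8
    core_amplitude: float = 4.0
    halo_amplitude: float = 1.0
    core_radius: float = 1.2
    halo_radius: float = 2.5
    noise_sd: float = 0.2
    group_fnc: tuple[np.ndarray, np.ndarray] | None = None
    n_subjects_per_group: int = 10
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_time <= 0 or self.n_sources <= 0:
            raise ConfigurationError("n_time and n_sources must be positive")
        if self.n_subjects_per_group <= 0:
            raise ConfigurationError("n_subjects_per_group must be positive")
        if not (0 <= self.halo_amplitude < self.core_amplitude):
            raise ConfigurationError(
                "halo_amplitude must lie in [0, core_amplitude)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not (0 < self.core_radius <= self.halo_radius):
            raise ConfigurationError("need 0 < core_radius <= halo_radius")
        if self.group_fnc is not None:
            fncs = tuple(np.asarray(C, dtype=float) for C in self.group_fnc)
            if len(fncs) != 2:
                raise ConfigurationError("group_fnc must hold two matrices")
            for C in fncs:
                _validate_corr(C)
                if C.shape[0] not in (self.n_sources, 2 * self.n_sources):
                    raise ConfigurationError(
                        "group_fnc side must be n_sources or 2*n_sources")
            if fncs[0].shape != fncs[1].shape:
                raise ConfigurationError("group_fnc matrices must match in size")
            self.group_fnc = fncs

    @property
    def paired(self) -> bool:
        """True when cores and halos carry separate time courses."""
        return (self.group_fnc is not None
                and self.group_fnc[0].shape[0] == 2 * self.n_sources)


@dataclass
class CohortGroundTruth:
    """Everything the generator knows: the oracle for downstream stages."""

    source_maps: list[SpatialMap]          # composite core+halo amplitude maps
    core_masks: list[np.ndarray]           # flat bool, True = core (AN) voxel
    halo_masks: list[np.ndarray]           # flat bool, True = halo (RIN ring)
    time_courses: list[np.ndarray]         # per subject, (n_tc, n_time)
    mixing: list[np.ndarray]               # per subject, (n_time, n_tc)
    clean_data: list[np.ndarray]           # per subject, mixing @ sources
    group_labels: np.ndarray               # per subject, 0 or 1
    paired: bool
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def n_subjects(self) -> int:
        return len(self.time_courses)

    def core_tc(self, subject: int, i: int) -> np.ndarray:
        """Time course driving source i's core for one subject."""
        return self.time_courses[subject][i]

    def halo_tc(self, subject: int, i: int) -> np.ndarray:
        """Time course driving source i's halo (== core TC when unpaired)."""
        n = len(self.source_maps)
        row = n + i if self.paired else i
        return self.time_courses[subject][row]


def _place_centers(config: SimulationConfig, rng: np.random.Generator):
    cell = max(int(np.ceil(2 * config.halo_radius)), 1)
    n_cells = [d // cell for d in config.grid_dims]
    total = int(np.prod(n_cells))
    if total < config.n_sources:
        raise ConfigurationError(
            f"grid {config.grid_dims} fits only {total} blobs of halo radius "
            f"{config.halo_radius}; {config.n_sources} requested")
    cells = np.array([(i, j, k)
                      for i in range(n_cells[0])
                      for j in range(n_cells[1])
                      for k in range(n_cells[2])])
    order = rng.permutation(total)[: config.n_sources]
    return cells[order] * cell + cell // 2


def generate_sources(config: SimulationConfig):
    """Place spherical core+halo sources on the grid.

    Returns a list of ``(source_map, core_mask)`` pairs: the map holds
    ``core_amplitude`` inside the core radius, ``halo_amplitude`` in the
    halo shell, 0 elsewhere; ``core_mask`` is the flat boolean AN oracle.
    """
    rng = np.random.default_rng(config.seed)
    centers = _place_centers(config, rng)
    grid = VolumeGrid(config.grid_dims)
    idx = MaskIndex(np.ones(config.grid_dims, dtype=bool))
    coords = idx.voxels.astype(float)
    out = []
    for s, c in enumerate(centers):
        dist = np.linalg.norm(coords - c, axis=1)
        core = dist <= config.core_radius
        halo = (dist > config.core_radius) & (dist <= config.halo_radius)
        values = np.zeros(idx.n_voxels)
        values[core] = config.core_amplitude
        values[halo] = config.halo_amplitude
        out.append((SpatialMap(values, idx, grid, label=f"source{s}"), core))
    return out


def _draw_timecourses(C: np.ndarray, n_time: int, ar: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Rows ~ N(0,1) with cross-correlation C (eigenfactor construction)."""
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((C.shape[0], n_time))
    if ar > 0:
        z = lfilter([1.0], [1.0, -ar], z, axis=1)
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    return L @ z


def generate_cohort(config: SimulationConfig):
    """Generate a two-group cohort of BoldRuns plus its ground truth.

    Per subject, time courses are drawn with the correlation structure of
    that subject's group, data are ``mixing @ sources`` plus Gaussian noise,
    and everything used is recorded in :class:`CohortGroundTruth`.
    """
    rng = np.random.default_rng(config.seed)
    src = generate_sources(config)
    maps = [m for m, _ in src]
    core_masks = [c for _, c in src]
    halo_masks = [(m.values > 0) & ~c for m, c in src]
    n = config.n_sources
    if config.group_fnc is None:
        fncs = (np.eye(n), np.eye(n))
    else:
        fncs = config.group_fnc
    paired = fncs[0].shape[0] == 2 * n

    # source matrix rows: the spatial patterns each time course drives
    if paired:
        S = np.vstack(
            [np.where(c, config.core_amplitude, 0.0) for c in core_masks]
            + [np.where(h, config.halo_amplitude, 0.0) for h in halo_masks])
    else:
        S = np.vstack([m.values for m in maps])

    labels = np.repeat([0, 1], config.n_subjects_per_group)
    runs, tcs, mixes, cleans = [], [], [], []
    for s, g in enumerate(labels):
        tc = _draw_timecourses(fncs[g], config.n_time, config.ar_coeff, rng)
        A = tc.T                                    # n_time x n_tc mixing
        clean = A @ S
        data = clean
        if config.noise_sd > 0:
            data = clean + config.noise_sd * rng.standard_normal(clean.shape)
        runs.append(BoldRun(data, maps[0].mask_index, maps[0].grid,
                            subject_id=f"sub-{s:03d}"))
        tcs.append(tc)
        mixes.append(A)
        cleans.append(clean)
    truth = CohortGroundTruth(maps, core_masks, halo_masks, tcs, mixes,
                              cleans, labels, paired, config)
    return runs, truth


@dataclass
class GuidedCohort:
    """Cohort whose subject maps deviate from the group references.

    Emulates inter-subject spatial variability: every subject's true source
    map is a controlled perturbation of the shared group map (correlation
    ``reference_r``), so reference-guided estimation can be scored against
    both the subject truth and the reference it started from.
    """

    runs: list[BoldRun]
    references: list[SpatialMap]          # group maps, z-scored
    subject_maps: list[list[SpatialMap]]  # per subject, z-scored truths
    time_courses: list[np.ndarray]


def generate_guided_cohort(config: SimulationConfig,
                           reference_r: float = 0.8) -> GuidedCohort:
    """Generate per-subject data from perturbed copies of the group sources.

    Each subject's map ``i`` is ``reference_r * ref_i + sqrt(1 - r^2) * u``
    with ``u`` an independent standard-normal field, then data are
    ``mixing @ subject_sources`` plus noise as in :func:`generate_cohort`.
    """
    if not (0 < reference_r < 1):
        raise ConfigurationError("reference_r must lie in (0, 1)")
    rng = np.random.default_rng(config.seed)
    src = generate_sources(config)
    refs = [m.zscored() for m, _ in src]
    n = config.n_sources
    fncs = config.group_fnc or (np.eye(n), np.eye(n))
    if fncs[0].shape[0] != n:
        raise ConfigurationError("guided cohorts need an n_sources-sided group_fnc")
    n_subjects = 2 * config.n_subjects_per_group
    labels = np.repeat([0, 1], config.n_subjects_per_group)
    runs, subject_maps, tcs = [], [], []
    beta = np.sqrt(1.0 - reference_r ** 2)
    amp = np.sqrt(config.core_amplitude * config.halo_amplitude) \
        if config.halo_amplitude > 0 else config.core_amplitude
    for s in range(n_subjects):
        maps_s = []
        for ref in refs:
            u = rng.standard_normal(ref.n_voxels)
            u = (u - u.mean()) / u.std()
            pert = reference_r * ref.values + beta * u
            maps_s.append(SpatialMap(pert, ref.mask_index, ref.grid,
                                     label=ref.label).zscored())
        tc = _draw_timecourses(fncs[labels[s]], config.n_time,
                               config.ar_coeff, rng)
        S = amp * np.vstack([m.values for m in maps_s])
        data = tc.T @ S
        if config.noise_sd > 0:
            data = data + config.noise_sd * rng.standard_normal(data.shape)
        runs.append(BoldRun(data, refs[0].mask_index, refs[0].grid,
                            subject_id=f"sub-{s:03d}"))
        subject_maps.append(maps_s)
        tcs.append(tc)
    return GuidedCohort(runs, refs, subject_maps, tcs)


def write_cohort(runs: list[BoldRun], truth: CohortGroundTruth, out_dir) -> None:
    """Write the cohort as NIfTI 4D files + mask + a JSON ground-truth sidecar."""
    from . import io as _io

    os.makedirs(out_dir, exist_ok=True)
    grid = runs[0].grid
    mask_vol = runs[0].mask_index.unmask(np.ones(runs[0].n_voxels))
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask_vol.astype(np.float32), grid.affine),
             os.path.join(out_dir, "mask.nii.gz"))
    for run in runs:
        vol4d = np.stack([run.mask_index.unmask(row) for row in run.data],
                         axis=-1).astype(np.float32)
        nib.save(nib.Nifti1Image(vol4d, grid.affine),
                 os.path.join(out_dir, f"{run.subject_id}_bold.nii.gz"))
    _io.maps_to_nifti(truth.source_maps, os.path.join(out_dir, "sources.nii.gz"))
    sidecar = {
        "group_labels": truth.group_labels.tolist(),
        "paired": truth.paired,
        "subjects": [r.subject_id for r in runs],
        "core_voxel_counts": [int(c.sum()) for c in truth.core_masks],
        "time_courses": [tc.tolist() for tc in truth.time_courses],
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(sidecar, fh)
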