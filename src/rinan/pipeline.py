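"""End-to-end workflow: simulate/ingest -> group ICA -> guided subject ICA
-> component screening -> AN/RIN splitting -> FNC statistics -> classification.

Each stage writes its artifacts into a run directory together with a
provenance record (config hash, seed, package version), so a run can be
resumed stage by stage from the command line or executed in one call via
:func:`run_pipeline`.  All numeric outputs are deterministic functions of
the validated :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .containers import BoldRun, MaskIndex, SpatialMap, VolumeGrid
from .classify import (STRATEGIES, StrategyComparison, SvmConfig,
                       features_from_splits)
from .fnc import FncGroupComparison, compute_fnc
from .gica import GroupICA
from .reference_ica import (GigIcaConfig, ReferenceICA, ReferenceSet,
                            compute_tc)
from .simulate import SimulationConfig, generate_cohort, make_group_fnc
from .split import make_mask, split_timecourses

logger = logging.getLogger(__name__)


class SimulateSection(BaseModel):
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    n_time: int = 150
    n_sources: int = 8
    core_amplitude: float = 4.0
    halo_amplitude: float = 1.0
    core_radius: float = 1.2
    halo_radius: float = 2.5
    noise_sd: float = 0.2
    n_subjects_per_group: int = 20
    paired: bool = True
    coupling: float = 0.6
    planted_edges: list[tuple[int, int, float]] = Field(default_factory=list)
    ar_coeff: float = 0.0


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    mu: float = 3.0
    mu_sweep: list[float] = Field(default_factory=lambda: [1.0, 2.0, 3.0, 4.0])
    a: float = 0.5
    n_components: Optional[int] = None
    icasso_repeats: int = 20
    alpha: float = 0.05
    fisher: bool = True
    strategies: list[str] = Field(default_factory=lambda: list(STRATEGIES))
    classify_repeats: int = 100
    n_selected_features: int = 20
    tr_seconds: float = 2.0
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    bold_paths: list[str] = Field(default_factory=list)
    mask_path: Optional[str] = None
    group_labels: list[int] = Field(default_factory=list)

    @field_validator("mu")
    @classmethod
    def _mu_positive(cls, v):
        if v <= 0:
            raise ValueError("mu must be positive")
        return v

    @field_validator("a")
    @classmethod
    def _a_open_unit(cls, v):
        if not (0 < v < 1):
            raise ValueError("a must lie in (0, 1)")
        return v

    @field_validator("strategies")
    @classmethod
    def _known_strategies(cls, v):
        for s in v:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        return v

    def validate_inputs(self) -> None:
        """Fail before any compute if external inputs are missing."""
        for p in self.bold_paths:
            if not os.path.exists(p):
                raise FileNotFoundError(f"bold input not found: {p}")
        if self.bold_paths and self.mask_path is None:
            raise ValueError("mask_path is required with bold_paths")
        if self.mask_path and not os.path.exists(self.mask_path):
            raise FileNotFoundError(f"mask not found: {self.mask_path}")
        if self.bold_paths and len(self.group_labels) != len(self.bold_paths):
            raise ValueError("group_labels must match bold_paths")

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()).hexdigest()[:16]


def simulation_config(cfg: RunConfig) -> SimulationConfig:
    s = cfg.simulate
    base = make_group_fnc(s.n_sources, paired=s.paired, coupling=s.coupling)
    planted = make_group_fnc(s.n_sources, paired=s.paired, coupling=s.coupling,
                             edges=s.planted_edges)
    return SimulationConfig(
        grid_dims=s.grid_dims, n_time=s.n_time, n_sources=s.n_sources,
        core_amplitude=s.core_amplitude, halo_amplitude=s.halo_amplitude,
        core_radius=s.core_radius, halo_radius=s.halo_radius,
        noise_sd=s.noise_sd, group_fnc=(base, planted),
        n_subjects_per_group=s.n_subjects_per_group, ar_coeff=s.ar_coeff,
        seed=cfg.seed)


class PipelineResult:
    """In-memory artifacts of one full run."""

    def __init__(self):
        self.runs: list[BoldRun] = []
        self.truth = None
        self.group_results = None
        self.references: ReferenceSet | None = None
        self.subject_results = None
        self.splits_by_mu: dict[float, list] = {}
        self.fnc_by_mode: dict[str, list] = {}
        self.comparison = None
        self.classification = None
        self.sweep_table: pd.DataFrame | None = None
        self.group_labels: np.ndarray | None = None


def _write_provenance(out_dir: str, cfg: RunConfig, stage: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "provenance.json")
    record = {}
    if os.path.exists(path):
        with open(path) as fh:
            record = json.load(fh)
    record[stage] = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                     "version": __version__}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)


def load_inputs(cfg: RunConfig, result: PipelineResult) -> None:
    """Simulate a cohort or ingest the configured NIfTI files."""
    if cfg.bold_paths:
        from .io import read_bold, read_mask

        mask = read_mask(cfg.mask_path)
        result.runs = [read_bold(p, mask, subject_id=f"sub-{i:03d}")
                       for i, p in enumerate(cfg.bold_paths)]
        result.group_labels = np.asarray(cfg.group_labels)
    else:
        runs, truth = generate_cohort(simulation_config(cfg))
        result.runs, result.truth = runs, truth
        result.group_labels = truth.group_labels


def run_decompose(cfg: RunConfig, result: PipelineResult) -> None:
    n_comp = cfg.n_components or (cfg.simulate.n_sources
                                  if result.truth is not None else None)
    model = GroupICA(result.runs, n_components=n_comp,
                     icasso_repeats=cfg.icasso_repeats)
    result.group_results = model.fit(seed=cfg.seed)


def make_references(cfg: RunConfig, result: PipelineResult) -> None:
    """Order the group maps as a reference set for guided subject ICA.

    On synthetic cohorts the group maps are matched one-to-one to the true
    source maps (restoring a meaningful network order and sign); otherwise
    the group maps are used in stability order.
    """
    from .select import match_to_icns

    maps = result.group_results.group_maps
    if result.truth is not None:
        icns = ReferenceSet([m.zscored() for m in result.truth.source_maps],
                            labels=[m.label for m in result.truth.source_maps])
        _, _, ordered = match_to_icns(maps, icns)
        result.references = ReferenceSet(ordered)
    else:
        result.references = ReferenceSet(maps)


def run_reconstruct(cfg: RunConfig, result: PipelineResult) -> None:
    model = ReferenceICA(result.runs, result.references,
                         GigIcaConfig(a=cfg.a, seed=cfg.seed))
    result.subject_results = model.fit()


def run_split(cfg: RunConfig, result: PipelineResult,
              mus: list[float] | None = None) -> None:
    """Split every subject x component at each mu (subject z-maps)."""
    mus = mus or [cfg.mu]
    for mu in mus:
        per_subject = []
        for run, sub in zip(result.runs, result.subject_results.subjects):
            splits = [split_timecourses(run, m, make_mask(m, mu))
                      for m in sub.maps]
            per_subject.append(splits)
        result.splits_by_mu[float(mu)] = per_subject


def run_fnc(cfg: RunConfig, result: PipelineResult,
            mu: float | None = None) -> None:
    mu = float(mu if mu is not None else cfg.mu)
    per_subject = result.splits_by_mu[mu]
    original = [sub.time_courses for sub in result.subject_results.subjects]
    result.fnc_by_mode = {
        "all": [compute_fnc(s, "all") for s in per_subject],
        "act": [compute_fnc(s, "act") for s in per_subject],
        "inert": [compute_fnc(s, "inert") for s in per_subject],
        "original": [compute_fnc(s, "original", tc)
                     for s, tc in zip(per_subject, original)],
    }


def run_compare(cfg: RunConfig, result: PipelineResult) -> None:
    labels = result.group_labels
    fncs = result.fnc_by_mode["all"]
    groupA = [f for f, g in zip(fncs, labels) if g == 0]
    groupB = [f for f, g in zip(fncs, labels) if g == 1]
    result.comparison = FncGroupComparison(groupA, groupB, alpha=cfg.alpha,
                                           fisher=cfg.fisher).fit()


def run_classify(cfg: RunConfig, result: PipelineResult,
                 mu: float | None = None) -> None:
    mu = float(mu if mu is not None else cfg.mu)
    per_subject = result.splits_by_mu[mu]
    original = [sub.time_courses for sub in result.subject_results.subjects]
    tables = {s: features_from_splits(per_subject, result.group_labels, s,
                                      original_tcs=original)
              for s in cfg.strategies}
    model = StrategyComparison(tables, n_repeats=cfg.classify_repeats,
                               config=SvmConfig(n_selected=cfg.n_selected_features))
    result.classification = model.fit()


def run_pipeline(cfg: RunConfig, out_dir: str | None = None) -> PipelineResult:
    """Execute every stage in order; artifacts land in ``out_dir`` if given."""
    cfg.validate_inputs()
    result = PipelineResult()
    stages = [("simulate", lambda: load_inputs(cfg, result)),
              ("decompose", lambda: run_decompose(cfg, result)),
              ("references", lambda: make_references(cfg, result)),
              ("reconstruct", lambda: run_reconstruct(cfg, result)),
              ("split", lambda: run_split(cfg, result)),
              ("fnc", lambda: run_fnc(cfg, result)),
              ("compare", lambda: run_compare(cfg, result)),
              ("classify", lambda: run_classify(cfg, result))]
    for name, fn in stages:
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        if out_dir:
            _write_provenance(out_dir, cfg, name)
    if out_dir:
        write_artifacts(cfg, result, out_dir)
    return result


def sweep_mu(cfg: RunConfig, out_dir: str | None = None,
             classify: bool = False) -> PipelineResult:
    """Repeat split/FNC/compare (optionally classify) over ``mu_sweep``.

    Returns the result with a summary table: per mu, AN sizes, significant
    edge counts, and (optionally) mean accuracies per strategy.
    """
    cfg.validate_inputs()
    result = PipelineResult()
    load_inputs(cfg, result)
    run_decompose(cfg, result)
    make_references(cfg, result)
    run_reconstruct(cfg, result)
    run_split(cfg, result, mus=cfg.mu_sweep)
    rows = []
    for mu in cfg.mu_sweep:
        run_fnc(cfg, result, mu=mu)
        run_compare(cfg, result)
        splits0 = result.splits_by_mu[float(mu)][0]
        row = {"mu": mu,
               "mean_an_voxels": float(np.mean([s.an_count for s in splits0])),
               "n_significant_edges": result.comparison.n_significant}
        if classify:
            run_classify(cfg, result, mu=mu)
            for name in cfg.strategies:
                row[f"acc_{name}"] = float(
                    result.classification.metric(name).mean())
        rows.append(row)
    result.sweep_table = pd.DataFrame(rows)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        result.sweep_table.to_csv(os.path.join(out_dir, "mu_sweep.tsv"),
                                  sep="\t", index=False)
        _write_provenance(out_dir, cfg, "sweep")
    return result


def write_artifacts(cfg: RunConfig, result: PipelineResult,
                    out_dir: str) -> None:
    """Persist the main artifacts as NIfTI / TSV / JSON."""
    from .io import maps_to_nifti, timecourses_to_tsv

    os.makedirs(out_dir, exist_ok=True)
    if result.group_results is not None:
        maps_to_nifti(result.group_results.group_maps,
                      os.path.join(out_dir, "group_maps.nii.gz"))
        result.group_results.summary().to_csv(
            os.path.join(out_dir, "group_ica_summary.tsv"), sep="\t",
            index=False)
    if result.subject_results is not None:
        sub0 = result.subject_results.subjects[0]
        timecourses_to_tsv(sub0.time_courses, [m.label for m in sub0.maps],
                           os.path.join(out_dir, "sub0_timecourses.tsv"))
    if result.splits_by_mu:
        mu = float(cfg.mu)
        if mu in result.splits_by_mu:
            splits = result.splits_by_mu[mu][0]
            tcs, labels = [], []
            for s in splits:
                la, li = s.labels
                tcs.extend([s.t_act, s.t_ine])
                labels.extend([la, li])
            timecourses_to_tsv(np.vstack(tcs), labels,
                               os.path.join(out_dir, "sub0_split_tcs.tsv"))
    if result.fnc_by_mode:
        result.fnc_by_mode["all"][0].to_frame().to_csv(
            os.path.join(out_dir, "sub0_fnc_all.tsv"), sep="\t")
    if result.comparison is not None:
        result.comparison.summary().to_csv(
            os.path.join(out_dir, "fnc_significant_edges.tsv"), sep="\t",
            index=False)
        result.comparison.alteration_counts().to_csv(
            os.path.join(out_dir, "fnc_alteration_counts.tsv"), sep="\t",
            index=False)
    if result.classification is not None:
        result.classification.summary().to_csv(
            os.path.join(out_dir, "classification_summary.tsv"), sep="\t",
            index=False)
        result.classification.long_format().to_csv(
            os.path.join(out_dir, "classification_long.csv"), index=False)
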