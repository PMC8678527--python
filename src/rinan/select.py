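"""Component screening and network identification.

Group components are filtered in three steps before any network analysis:

1. tissue screen — components correlating more with white-matter or CSF
   priors than with gray matter (or barely with gray matter at all) are
   artefactual and excluded;
2. spectral screen — resting-state networks live in the low-frequency BOLD
   band, so the ratio of periodogram power below ``split_hz`` to power above
   it must be high (canonical networks show ratios well above 10);
3. template matching — survivors are assigned one-to-one to the reference
   intrinsic connectivity networks (ICNs) by maximising total absolute
   spatial correlation (optimal linear assignment), sign-flipping candidates
   whose matched correlation is negative.

Peak activation coordinates (voxel and world mm) are reported per map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import periodogram

from .containers import SpatialMap
from .reference_ica import ReferenceSet

logger = logging.getLogger(__name__)

#: canonical network order used when relabelling matched components
ICN_ORDER = ["MVN", "LO", "Auditory", "Sensorimotor",
             "DMN", "ECN", "RFPN", "LFPN"]


@dataclass
class TissueRule:
    """Exclusion rule: keep a component only if it is gray-matter dominant."""

    min_gm_r: float = 0.05
    exclude_if_wm_exceeds_gm: bool = True
    exclude_if_csf_exceeds_gm: bool = True

    def keep(self, gm_r, wm_r, csf_r) -> bool:
        if gm_r is None:
            return True
        if gm_r < self.min_gm_r:
            return False
        if self.exclude_if_wm_exceeds_gm and wm_r is not None and wm_r > gm_r:
            return False
        if self.exclude_if_csf_exceeds_gm and csf_r is not None and csf_r > gm_r:
            return False
        return True


@dataclass
class SelectionReport:
    """Per-component screening record."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def selected_indices(self) -> list[int]:
        return self.table.index[self.table["selected"]].tolist()


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def tissue_screen(maps: list[SpatialMap],
                  gm: SpatialMap | None, wm: SpatialMap | None,
                  csf: SpatialMap | None,
                  rule: TissueRule | None = None) -> pd.DataFrame:
    """Correlate each component with the tissue priors and apply the rule.

    Missing priors are skipped with a warning (their criterion is not
    enforced).  Returns a DataFrame with columns ``gm_r, wm_r, csf_r,
    tissue_pass``.
    """
    rule = rule or TissueRule()
    for name, prior in (("gray matter", gm), ("white matter", wm),
                        ("CSF", csf)):
        if prior is None:
            logger.warning("no %s prior supplied; criterion skipped", name)
    rows = []
    for m in maps:
        gm_r = _safe_corr(m.values, gm.values) if gm is not None else None
        wm_r = _safe_corr(m.values, wm.values) if wm is not None else None
        csf_r = _safe_corr(m.values, csf.values) if csf is not None else None
        rows.append({"component": m.label, "gm_r": gm_r, "wm_r": wm_r,
                     "csf_r": csf_r, "tissue_pass": rule.keep(gm_r, wm_r, csf_r)})
    return pd.DataFrame(rows)


RATIO_CAP = 1e12


def spectral_ratio(tc: np.ndarray, tr_seconds: float,
                   split_hz: float = 0.10) -> float:
    """Low-to-high frequency power ratio of a component time course.

    Periodogram power summed over ``(0, split_hz]`` divided by power over
    ``(split_hz, Nyquist]``; the zero-frequency bin is excluded.  A near-zero
    denominator is reported as the cap ``1e12``.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.size < 8:
        raise ValueError("need at least 8 time points")
    nyquist = 0.5 / tr_seconds
    if split_hz >= nyquist:
        raise ValueError(f"split_hz {split_hz} must be below Nyquist {nyquist}")
    freqs, power = periodogram(tc, fs=1.0 / tr_seconds)
    low = power[(freqs > 0) & (freqs <= split_hz)].sum()
    high = power[freqs > split_hz].sum()
    if high <= low * 1e-12 or high == 0:
        return RATIO_CAP
    return float(low / high)


def match_to_icns(candidates: list[SpatialMap], icns: ReferenceSet):
    """Assign candidates to reference ICNs by optimal |correlation| matching.

    Returns ``(assignment, correlations, signed_maps)`` where ``assignment``
    maps ICN index -> candidate index, ``correlations`` holds the matched
    (post sign-correction, hence nonnegative for true matches) Pearson r,
    and ``signed_maps`` are the matched candidates relabelled in ICN order
    with negative-correlation candidates sign-flipped.
    """
    n_icn = len(icns)
    n_cand = len(candidates)
    if n_cand < n_icn:
        warnings.warn(f"only {n_cand} candidates for {n_icn} ICNs; "
                      "partial assignment returned")
    C = np.zeros((n_icn, n_cand))
    for i, ref in enumerate(icns.references):
        for j, cand in enumerate(candidates):
            C[i, j] = _safe_corr(ref.values, cand.values)
    rows, cols = linear_sum_assignment(-np.abs(C))
    assignment = {int(i): int(j) for i, j in zip(rows, cols)}
    corrs, signed_maps = {}, []
    for i in sorted(assignment):
        j = assignment[i]
        r = C[i, j]
        sign = -1.0 if r < 0 else 1.0
        cand = candidates[j]
        signed_maps.append(SpatialMap(sign * cand.values, cand.mask_index,
                                      cand.grid, label=icns.labels[i]))
        corrs[i] = float(abs(r))
    return assignment, corrs, signed_maps


def peak_coordinate(spatial_map: SpatialMap):
    """Location of the maximum value: (voxel ijk, world mm, value).

    Ties are broken by the lowest linear (Fortran) index; an all-equal map
    triggers a warning and returns its first voxel.
    """
    v = spatial_map.values
    if v.size == 0:
        raise ValueError("empty map")
    if np.all(v == v[0]):
        warnings.warn("all-equal map; peak reported at the first voxel")
    k = int(np.argmax(v))
    ijk = spatial_map.mask_index.voxels[k]
    world = spatial_map.grid.voxel_to_world(ijk)
    return tuple(int(x) for x in ijk), tuple(float(x) for x in world), float(v[k])


def screen_components(maps: list[SpatialMap], time_courses: np.ndarray,
                      tr_seconds: float, icns: ReferenceSet,
                      gm: SpatialMap | None = None,
                      wm: SpatialMap | None = None,
                      csf: SpatialMap | None = None,
                      tissue_rule: TissueRule | None = None,
                      split_hz: float = 0.10,
                      ratio_threshold: float = 10.0) -> SelectionReport:
    """Run the full three-step screen and rank the matched components.

    ``selected`` marks the components that pass both screens and win the
    assignment to a reference ICN; ``rank`` is the ICN index (network order)
    or None.  Selection is invariant to candidate ordering and sign.
    """
    df = tissue_screen(maps, gm, wm, csf, tissue_rule)
    df["power_ratio"] = [spectral_ratio(tc, tr_seconds, split_hz)
                         for tc in np.atleast_2d(time_courses)]
    df["spectral_pass"] = df["power_ratio"] > ratio_threshold
    keep = df["tissue_pass"] & df["spectral_pass"]
    survivors = [i for i in range(len(maps)) if keep.iloc[i]]
    df["best_icn"] = None
    df["icn_r"] = np.nan
    df["selected"] = False
    df["rank"] = None
    if survivors:
        assignment, corrs, _ = match_to_icns([maps[i] for i in survivors], icns)
        for icn_idx, cand_idx in assignment.items():
            orig = survivors[cand_idx]
            df.loc[orig, "best_icn"] = icns.labels[icn_idx]
            df.loc[orig, "icn_r"] = corrs[icn_idx]
            df.loc[orig, "selected"] = True
            df.loc[orig, "rank"] = icn_idx
    return SelectionReport(df)
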