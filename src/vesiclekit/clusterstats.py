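"""Vesicle-clustering quantitation and condition comparisons.

Covers the statistics of the clustering assay: classification of normalized
spot intensities into singles (< 1.5 a.u.) and clusters (>= 2 a.u., up to
~6 a.u.), counting of v-/v-vesicle interactions on the DiI channel after the
DiD surface passes a saturation/homogeneity check, dose-response and mutant
comparisons with the classical (pooled-variance) Student's t-test, the
finite-volume depletion relation — clustering k vesicles into one particle
divides the free-particle count by the mean cluster size — and flotation
percent-bound arithmetic (top two of eight gradient fractions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .presets import ConditionPreset, mean_multiplicity
from .spotdetect import (DEFAULT_MAX_AREA_PX, DEFAULT_MAX_AU, FieldCounts,
                         count_per_fov, detect_spots, exclude_large_spots,
                         normalize_au)
from .synthgen import TwoChannelField, render_clustering_field

logger = logging.getLogger("vesiclekit")

__all__ = [
    "ClassifierParams",
    "ComparisonResult",
    "classify_spots",
    "surface_homogeneity",
    "count_vv_interactions",
    "students_t",
    "significance_stars",
    "depletion_spot_count",
    "anticorrelation_report",
    "flotation_percent_bound",
    "dose_response_table",
]

HOMOGENEITY_CV_THRESHOLD = 0.2
DEFAULT_BLOCK_PX = 128


@dataclass(frozen=True)
class ClassifierParams:
    """Intensity thresholds (a.u.) separating singles from clusters.

    The single-vesicle major peak sits below 1.5 a.u. and the cluster tail
    starts above 2 a.u.; spots in the [1.5, 2.0) gap are reported as a
    separate intermediate class and pooled with clusters in summary totals.
    """

    single_max_au: float = 1.5
    cluster_min_au: float = 2.0
    cluster_range_max_au: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.single_max_au <= self.cluster_min_au <= self.cluster_range_max_au:
            raise ValueError("thresholds must satisfy 0 < single <= cluster_min <= cluster_max")


@dataclass
class ComparisonResult:
    """Two-condition comparison by the classical Student's t-test."""

    label_a: str
    label_b: str
    counts_a: FieldCounts
    counts_b: FieldCounts
    t: float
    df: int
    p: float
    stars: str = field(init=False)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.stars = significance_stars(self.p)


def classify_spots(spots, params: ClassifierParams | None = None) -> dict[str, int]:
    """Count singles / intermediate / clusters from normalized intensities.

    Returns a dict with the three classes plus ``clusters_total`` (clusters +
    intermediate, the "brighter spots between 1.5 and 6 a.u." population).
    """
    params = params or ClassifierParams()
    au = np.array([s.intensity_au for s in spots], dtype=float)
    if au.size and not np.all(np.isfinite(au)):
        raise ValueError("spots must carry normalized intensities (run normalize_au)")
    singles = int(np.sum(au < params.single_max_au))
    clusters = int(np.sum(au >= params.cluster_min_au))
    intermediate = int(au.size) - singles - clusters
    return {"singles": singles, "intermediate": intermediate, "clusters": clusters,
            "clusters_total": clusters + intermediate}


def surface_homogeneity(frame: np.ndarray, block_px: int = DEFAULT_BLOCK_PX) -> float:
    """Coefficient of variation of block-summed intensities on a regular grid.

    A saturated, homogeneously covered surface has low CV; the acceptance
    threshold is CV < 0.2.  Partial edge blocks are ignored.
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape[0] // block_px, frame.shape[1] // block_px
    if ny < 1 or nx < 1:
        raise ValueError("frame smaller than one homogeneity block")
    trimmed = frame[:ny * block_px, :nx * block_px]
    blocks = trimmed.reshape(ny, block_px, nx, block_px).sum(axis=(1, 3))
    mean = blocks.mean()
    if mean == 0:
        return float("inf")
    return float(blocks.std() / mean)


def count_vv_interactions(fields: Sequence[TwoChannelField], psf_sigma_px: float = 1.3,
                          k_thresh: float = 5.0, min_sep_px: int = 3,
                          max_au: float = DEFAULT_MAX_AU,
                          max_area_px: int = DEFAULT_MAX_AREA_PX,
                          block_px: int = DEFAULT_BLOCK_PX,
                          cv_threshold: float = HOMOGENEITY_CV_THRESHOLD) -> FieldCounts:
    """Count docked DiI spots per imaging location, after large-spot exclusion.

    Each location's DiD surface must pass the saturation/homogeneity check
    first; a failing surface invalidates the simple per-location averaging
    and raises, naming the field.
    """
    counts = []
    for i, fld in enumerate(fields):
        cv = surface_homogeneity(fld.did.frames[0], block_px=block_px)
        if cv >= cv_threshold:
            raise ValueError(f"field {i}: DiD surface fails homogeneity check "
                             f"(CV = {cv:.3f} >= {cv_threshold})")
        spots = detect_spots(fld.dii.frames[0], psf_sigma_px=psf_sigma_px,
                             k_thresh=k_thresh, min_sep_px=min_sep_px, fov_id=i)
        if spots:
            with warnings.catch_warnings():
                # sparse control fields (< 20 spots) legitimately fall back to
                # the median anchor; no need to warn per location
                warnings.simplefilter("ignore", UserWarning)
                spots = normalize_au(spots)
            kept, _ = exclude_large_spots(spots, max_au=max_au, max_area_px=max_area_px)
        else:
            kept = []
        counts.append(len(kept))
    logger.info("count_vv_interactions: counts per location = %s", counts)
    return count_per_fov(counts)


def significance_stars(p: float) -> str:
    """Significance convention: *** for p < 0.001 (as printed), ** / * below."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def students_t(a: Sequence[float], b: Sequence[float], label_a: str = "a",
               label_b: str = "b") -> ComparisonResult:
    """Two-sample equal-variance Student's t-test, two-tailed.

    Pooled-variance statistic with df = N1 + N2 - 2.  Zero pooled variance
    with equal means gives t = 0, p = 1; with unequal means the comparison is
    flagged degenerate (infinite t, p = 0).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    n1, n2 = xa.size, xb.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * xa.var(ddof=1) + (n2 - 1) * xb.var(ddof=1)) / df
    delta = xa.mean() - xb.mean()
    degenerate = False
    if pooled_var == 0:
        if delta == 0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(delta)) * float("inf"), 0.0
            degenerate = True
            logger.warning("students_t: zero pooled variance with unequal means")
    else:
        se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        t = float(delta / se)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return ComparisonResult(label_a=label_a, label_b=label_b,
                            counts_a=FieldCounts(list(xa)), counts_b=FieldCounts(list(xb)),
                            t=t, df=df, p=p, degenerate=degenerate)


def depletion_spot_count(n_vesicles: float, cluster_size_law: Mapping[int, float]) -> float:
    """Expected free-particle count after clustering in a finite volume.

    With a fixed vesicle budget, grouping vesicles into clusters of mean size
    E[k] leaves n_vesicles / E[k] independent particles — the mass-balance
    explanation for fewer fluorescent spots under clustering.
    """
    if n_vesicles <= 0:
        raise ValueError("n_vesicles must be positive")
    total = sum(cluster_size_law.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("cluster_size_law must sum to 1")
    return float(n_vesicles / mean_multiplicity(cluster_size_law))


def anticorrelation_report(clustering: Mapping[str, FieldCounts],
                           associations: Mapping[str, FieldCounts]
                           ) -> tuple[pd.DataFrame, float]:
    """Pair per-condition clustering and v-/t-association means; Spearman rho.

    Only ordinal structure is claimed (conditions that cluster more show
    fewer v-/t-vesicle associations), so a rank correlation is used.
    """
    if set(clustering) != set(associations):
        raise ValueError("clustering and association tables must cover the same conditions")
    conditions = list(clustering)
    table = pd.DataFrame({
        "condition": conditions,
        "clustering_mean": [clustering[c].mean for c in conditions],
        "association_mean": [associations[c].mean for c in conditions],
    })
    rho = float(stats.spearmanr(table["clustering_mean"], table["association_mean"]).statistic)
    return table, rho


def flotation_percent_bound(fraction_signals: Sequence[float]) -> float:
    """Percent lipid-bound protein: top two of eight gradient fractions over the total."""
    vals = np.asarray(fraction_signals, dtype=float)
    if vals.size != 8:
        raise ValueError("expected exactly 8 gradient fractions (top to bottom)")
    if np.any(vals < 0):
        raise ValueError("fraction signals must be non-negative")
    total = vals.sum()
    if total == 0:
        raise ValueError("all fraction signals are zero")
    return float(100.0 * vals[:2].sum() / total)


def dose_response_table(presets_by_conc: Mapping[float, ConditionPreset],
                        n_locations: int, surface_preset: ConditionPreset,
                        rng=None) -> pd.DataFrame:
    """Simulate the concentration series and tabulate counts with t-tests.

    Renders ``n_locations`` two-channel fields per concentration, counts DiI
    spots per location, and compares each concentration against the lowest
    (control) by Student's t-test.
    """
    if len(presets_by_conc) < 2:
        raise ValueError("need at least 2 concentrations")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    concs = sorted(presets_by_conc)
    counts: dict[float, FieldCounts] = {}
    for conc in concs:
        fields = [render_clustering_field(surface_preset, presets_by_conc[conc], rng)
                  for _ in range(n_locations)]
        counts[conc] = count_vv_interactions(fields)
    control = counts[concs[0]]
    rows = []
    for conc in concs:
        fc = counts[conc]
        if conc == concs[0]:
            t = p = float("nan")
            stars = ""
        else:
            cmp_res = students_t(fc.counts, control.counts,
                                 label_a=str(conc), label_b=str(concs[0]))
            t, p, stars = cmp_res.t, cmp_res.p, cmp_res.stars
        rows.append({"concentration": conc, "n": fc.n, "mean": fc.mean, "sd": fc.sd,
                     "t_vs_control": t, "p_vs_control": p, "stars": stars})
    return pd.DataFrame(rows)
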