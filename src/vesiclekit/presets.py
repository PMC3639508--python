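"""Experimental-condition presets for the synthetic single-vesicle generator.

Each preset bundles every parameter needed to emulate one condition of the
single-vesicle TIRF experiments: the expected number of docked vesicle spots
per field of view, the per-spot fusion probability within the 50-s observation
window, the bi-exponential event-time law, the vesicle cluster-size law, the
dequenching gain of the self-quenched content dye, and the optics/noise model.

The two fusion presets carry the published fitted kinetics and event/docked
ratios (166 of ~2000 docked vesicles without α-synuclein; 84 of ~1300 with
2 µM α-synuclein).  The clustering presets encode the relative clustering
efficiencies of the wildtype protein, the Parkinson's-disease point mutants
(A30P at half the wildtype efficiency; E46K and A53T at wildtype level), and
the negative controls (no α-Syn, no synaptobrevin-2, pure-PC membranes, and
the synaptobrevin-binding-deficient 1-95 truncation), all of which fall to
the no-α-Syn background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

__all__ = [
    "Optics",
    "NoiseModel",
    "ConditionPreset",
    "PRESET_NAMES",
    "make_preset",
    "truncated_geometric_law",
    "mean_multiplicity",
    "load_preset_overrides",
]


@dataclass(frozen=True)
class Optics:
    """Image-formation parameters shared by all synthetic renders."""

    psf_sigma_px: float = 1.3          # Gaussian PSF width (~80 nm vesicles are sub-resolution point emitters)
    field_size_px: int = 512
    frame_interval_s: float = 1.0
    n_pre_frames: int = 5              # docked spots are counted on these pre-trigger frames
    n_obs_frames: int = 51             # frames at t = 0..50 s; the closing frame guarantees
                                       # every event in [0, 50) lands on at least one frame
    min_sep_factor: float = 4.0        # minimum spot center separation, in units of psf_sigma_px
    border_px: int = 12                # keep-out margin so photometry discs never clip the frame

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_obs_frames < 1 or self.n_pre_frames < 0:
            raise ValueError("frame counts must be non-negative (>=1 observation frame)")

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_obs_frames


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: constant background, optional Poisson shot noise, Gaussian read noise."""

    background: float = 100.0
    shot_noise: bool = True
    read_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.background < 0 or self.read_sigma < 0:
            raise ValueError("background and read_sigma must be non-negative")


def truncated_geometric_law(q: float, k_max: int = 6) -> dict[int, float]:
    """Cluster-multiplicity law P(k) ∝ q**(k-1) on k = 1..k_max.

    A decaying geometric tail truncated at k_max = 6 mirrors the observed
    cluster intensity range (brighter spots between 1.5 and 6 a.u.); very
    large aggregates are a separate rare process.
    """
    if not 0 <= q < 1:
        raise ValueError("q must be in [0, 1)")
    if q == 0:
        return {1: 1.0}
    weights = {k: q ** (k - 1) for k in range(1, k_max + 1)}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


def mean_multiplicity(law: Mapping[int, float]) -> float:
    """E[k] of a cluster-size law."""
    return float(sum(k * p for k, p in law.items()))


@dataclass(frozen=True)
class ConditionPreset:
    name: str
    n_docked: float                     # expected docked-spot count per field of view
    n_fields: int = 10                  # imaging locations pooled per condition
    p_fusion: float = 0.0               # per-spot probability of a content-mixing event in the window
    kinetic_params: tuple[float, float, float, float, float] | None = None  # (y0, A1, tau1_s, A2, tau2_s)
    cluster_size_law: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    large_aggregate_rate: float = 0.0   # expected very-large-spot count per field
    dequench_factor: float = 2.0        # post/pre content intensity ratio (~twofold dye dilution)
    clustering_efficiency: float | None = None  # expected above-background docked DiI count per field
    flux_per_vesicle: float = 3000.0    # integrated counts per frame per single vesicle
    optics: Optics = field(default_factory=Optics)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fusion <= 1.0:
            raise ValueError("p_fusion must be in [0, 1]")
        if self.n_docked < 0 or self.large_aggregate_rate < 0 or self.n_fields < 1:
            raise ValueError("counts must be non-negative (n_fields >= 1)")
        if self.dequench_factor <= 1.0:
            raise ValueError("dequench_factor must exceed 1 (dequenching is an intensity gain)")
        total = sum(self.cluster_size_law.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"cluster_size_law must sum to 1 over k >= 1 (got {total})")
        if any(k < 1 for k in self.cluster_size_law):
            raise ValueError("cluster multiplicities must be >= 1")
        if self.kinetic_params is not None:
            _y0, a1, tau1, a2, tau2 = self.kinetic_params
            if not tau1 > tau2 > 0:
                raise ValueError("kinetic time constants must satisfy tau1 > tau2 > 0")
            if a1 < 0 or a2 < 0:
                raise ValueError("kinetic amplitudes must be non-negative")

    @property
    def observation_window_s(self) -> float:
        return (self.optics.n_obs_frames - 1) * self.optics.frame_interval_s


# Published bi-exponential fits of the fusion-event histograms, (y0, A1, tau1_s, A2, tau2_s).
KINETICS_NO_SYN = (-0.0046, 0.048, 27.1, 0.26, 0.58)
KINETICS_SYN_2UM = (-0.001, 0.064, 15.4, 0.22, 0.51)

_FUSION_OPTICS = Optics(min_sep_factor=6.0)
_SNAPSHOT_OPTICS = Optics(n_pre_frames=0, n_obs_frames=1)

_CLUSTER_BACKGROUND = 20.0   # nonspecific docked DiI spots per field without α-Syn
_EFF_WT_20UM = 380.0
_EFF_WT_2UM = 150.0

_LAW_SINGLES = truncated_geometric_law(0.0)
_LAW_BACKGROUND = truncated_geometric_law(0.05)
_LAW_MODERATE = truncated_geometric_law(0.35)
_LAW_STRONG = truncated_geometric_law(0.55)


def _cluster_preset(name: str, efficiency: float, law: Mapping[int, float],
                    large_rate: float) -> ConditionPreset:
    return ConditionPreset(
        name=name,
        n_docked=_CLUSTER_BACKGROUND + efficiency,
        clustering_efficiency=efficiency,
        cluster_size_law=law,
        large_aggregate_rate=large_rate,
        optics=_SNAPSHOT_OPTICS,
    )


def _build_presets() -> dict[str, ConditionPreset]:
    presets: dict[str, ConditionPreset] = {}
    presets["fusion_noSyn"] = ConditionPreset(
        name="fusion_noSyn",
        n_docked=200.0, n_fields=10,            # ~2000 docked vesicles pooled over 10 fields
        p_fusion=166.0 / 2000.0,
        kinetic_params=KINETICS_NO_SYN,
        cluster_size_law=_LAW_SINGLES,
        optics=_FUSION_OPTICS,
    )
    presets["fusion_Syn2uM"] = ConditionPreset(
        name="fusion_Syn2uM",
        n_docked=130.0, n_fields=10,            # ~1300 docked vesicles pooled over 10 fields
        p_fusion=84.0 / 1300.0,
        kinetic_params=KINETICS_SYN_2UM,
        cluster_size_law=_LAW_SINGLES,
        optics=_FUSION_OPTICS,
    )
    presets["cluster_noSyn"] = _cluster_preset("cluster_noSyn", 0.0, _LAW_BACKGROUND, 0.0)
    presets["cluster_WT_2uM"] = _cluster_preset("cluster_WT_2uM", _EFF_WT_2UM, _LAW_MODERATE, 1.0)
    presets["cluster_WT_20uM"] = _cluster_preset("cluster_WT_20uM", _EFF_WT_20UM, _LAW_STRONG, 2.0)
    # A30P is lipid-binding deficient: half the wildtype clustering efficiency.
    presets["cluster_A30P"] = _cluster_preset("cluster_A30P", _EFF_WT_20UM / 2.0, _LAW_MODERATE, 1.0)
    presets["cluster_E46K"] = _cluster_preset("cluster_E46K", _EFF_WT_20UM, _LAW_STRONG, 2.0)
    presets["cluster_A53T"] = _cluster_preset("cluster_A53T", _EFF_WT_20UM, _LAW_STRONG, 2.0)
    # Controls that abolish specific clustering: no synaptobrevin-2, no anionic lipid,
    # and the synaptobrevin-binding-deficient truncation all fall to background.
    presets["cluster_noSyb2"] = _cluster_preset("cluster_noSyb2", 0.0, _LAW_BACKGROUND, 0.0)
    presets["cluster_PConly"] = _cluster_preset("cluster_PConly", 0.0, _LAW_BACKGROUND, 0.0)
    presets["cluster_Syn1-95"] = _cluster_preset("cluster_Syn1-95", 0.0, _LAW_BACKGROUND, 0.0)
    presets["saturated_surface"] = ConditionPreset(
        name="saturated_surface",
        n_docked=2500.0,                        # saturated immobilized DiD layer, >1000 vesicles
        cluster_size_law=_LAW_SINGLES,
        optics=_SNAPSHOT_OPTICS,
    )
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(_PRESETS)

_NESTED_FIELDS = {"optics": Optics, "noise": NoiseModel}


def make_preset(name: str, **overrides) -> ConditionPreset:
    """Return the documented preset for a condition label, optionally overridden.

    Overrides replace top-level preset fields; ``optics`` and ``noise`` may be
    given as dicts, which are merged into the preset's existing values.
    """
    if name not in _PRESETS:
        valid = ", ".join(sorted(_PRESETS))
        raise KeyError(f"unknown preset {name!r}; valid presets: {valid}")
    preset = _PRESETS[name]
    if not overrides:
        return preset
    kwargs = {}
    for key, value in overrides.items():
        if key in _NESTED_FIELDS and isinstance(value, Mapping):
            kwargs[key] = replace(getattr(preset, key), **value)
        else:
            kwargs[key] = value
    return replace(preset, **kwargs)


def load_preset_overrides(path) -> dict[str, ConditionPreset]:
    """Load per-preset overrides from a YAML file: {preset_name: {field: value, ...}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("preset override file must map preset names to field dicts")
    return {name: make_preset(name, **(fields or {})) for name, fields in raw.items()}
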