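"""Synthetic single-vesicle TIRF data with known ground truth.

Generates the raw observables of the two assays this package analyzes:

* content-mixing fusion movies — fields of diffraction-limited docked-vesicle
  spots whose self-quenched content dye steps up ~twofold when a vesicle
  fuses, sampled in time from a bi-exponential event-time law;
* clustering snapshots — a saturated, homogeneous DiD-labeled immobilized
  layer plus a sparser DiI channel of docked vesicles/clusters whose count
  scales with the condition's clustering efficiency.

Image formation is deliberately minimal: isotropic Gaussian point-spread
function (vesicles of ~80 nm are far below the diffraction limit), constant
background, Poisson shot noise and Gaussian read noise.  Every stochastic
operation takes an explicit numpy Generator; with a fixed seed all outputs
are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .presets import ConditionPreset, make_preset

__all__ = [
    "Movie",
    "SpotTruth",
    "GroundTruth",
    "TwoChannelField",
    "sample_event_times",
    "synth_trace",
    "place_spots",
    "render_movie",
    "render_clustering_field",
    "render_fusion_fixture",
]

AGGREGATE_SIGMA_FACTOR = 2.5    # very large aggregates render wider than the PSF
AGGREGATE_K_RANGE = (15.0, 40.0)  # and far brighter than the 6-vesicle cluster range


@dataclass
class Movie:
    """Time-ordered stack of 2-D intensity frames."""

    frames: np.ndarray              # (n_frames, H, W)
    frame_interval_s: float = 1.0
    n_pre_frames: int = 0           # frames recorded before the Ca2+ trigger

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("Movie.frames must be a (n_frames, H, W) array")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SpotTruth:
    """Ground truth for one planted spot (testing sidecar)."""

    x: float
    y: float
    k: int = 1
    fused: bool = False
    t_event_s: float | None = None
    baseline: float = 0.0           # integrated flux per frame before any event
    is_aggregate: bool = False

    def __post_init__(self) -> None:
        if self.fused != (self.t_event_s is not None):
            raise ValueError("t_event_s must be present iff the spot is fused")


@dataclass
class GroundTruth:
    spots: list[SpotTruth] = field(default_factory=list)
    preset_name: str = ""

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_fused(self) -> int:
        return sum(s.fused for s in self.spots)

    def to_json(self, path) -> None:
        payload = {
            "preset": self.preset_name,
            "spots": [asdict(s) for s in self.spots],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(spots=[SpotTruth(**s) for s in payload["spots"]],
                   preset_name=payload.get("preset", ""))


@dataclass
class TwoChannelField:
    """One clustering-assay imaging location: DiD surface + DiI docked channel."""

    did: Movie
    dii: Movie
    truth: GroundTruth


def _as_rng(rng, preset: ConditionPreset | None = None) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(preset.seed if preset is not None else None)
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Event-time law
# ---------------------------------------------------------------------------

def sample_event_times(preset: ConditionPreset, n_events: int, rng=None) -> np.ndarray:
    """Draw fusion-event times (s) from the preset's bi-exponential law.

    Times are i.i.d. from the density proportional to
    ``A1*exp(-t/tau1) + A2*exp(-t/tau2)`` truncated to the observation window
    [0, W) (W = 50 s by default).  The fitted offset y0 is a baseline artifact
    and is ignored: a density must be non-negative.  Each exponential
    component is selected with probability proportional to its truncated mass
    ``Ai * taui * (1 - exp(-W/taui))``.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = _as_rng(rng, preset)
    if n_events == 0:
        return np.empty(0)
    if preset.kinetic_params is None:
        raise ValueError(f"preset {preset.name!r} has no kinetic parameters")
    _y0, a1, tau1, a2, tau2 = preset.kinetic_params
    if a1 == 0 and a2 == 0:
        raise ValueError("both kinetic amplitudes are zero; the event-time law is undefined")
    window = preset.observation_window_s
    taus = np.array([tau1, tau2])
    masses = np.array([a1, a2]) * taus * (1.0 - np.exp(-window / taus))
    weights = masses / masses.sum()
    comp = rng.choice(2, size=n_events, p=weights)
    tau = taus[comp]
    u = rng.random(n_events)
    # inverse CDF of an exponential truncated to [0, window)
    return -tau * np.log1p(-u * (1.0 - np.exp(-window / tau)))


# ---------------------------------------------------------------------------
# Per-spot traces
# ---------------------------------------------------------------------------

def _event_frame_index(preset: ConditionPreset, event_time_s: float) -> int:
    """Absolute index of the first frame at or after the event time."""
    opt = preset.optics
    return opt.n_pre_frames + math.ceil(event_time_s / opt.frame_interval_s)

def _clean_flux(preset: ConditionPreset, k: int, fused: bool,
                event_time_s: float | None) -> np.ndarray:
    """Noise-free integrated flux per frame for one spot.

    A spot of multiplicity k carries k vesicles' worth of content dye; upon
    fusion the fusing vesicle's content is diluted ~twofold and dequenches, so
    the level steps from ``k`` to ``k - 1 + dequench_factor`` vesicle units.
    """
    opt = preset.optics
    flux = np.full(opt.n_frames, float(k) * preset.flux_per_vesicle)
    if fused:
        i = _event_frame_index(preset, event_time_s)
        post = (k - 1 + preset.dequench_factor) * preset.flux_per_vesicle
        if i < opt.n_frames:
            flux[i:] = post
    return flux


def synth_trace(preset: ConditionPreset, fused: bool, event_time_s: float | None = None,
                rng=None, k: int = 1) -> tuple[np.ndarray, SpotTruth]:
    """Synthesize one per-spot content-dye intensity trace plus its ground truth.

    The trace is the integrated spot intensity at 1-s frame intervals:
    constant at baseline, multiplied by the dequench factor from the first
    frame at or after the event time onward, with the preset's noise model
    applied.  No downward steps are generated.
    """
    if fused:
        if event_time_s is None:
            raise ValueError("fused traces need an event time")
        if not 0.0 <= event_time_s <= preset.observation_window_s:
            raise ValueError("event_time_s must lie within the observation window")
    rng = _as_rng(rng, preset)
    clean = _clean_flux(preset, k, fused, event_time_s)
    noisy = rng.poisson(clean).astype(float) if preset.noise.shot_noise else clean.copy()
    if preset.noise.read_sigma > 0:
        noisy = noisy + rng.normal(0.0, preset.noise.read_sigma, size=clean.shape)
    truth = SpotTruth(x=float("nan"), y=float("nan"), k=k, fused=fused,
                      t_event_s=event_time_s if fused else None,
                      baseline=float(k) * preset.flux_per_vesicle)
    return noisy, truth


# ---------------------------------------------------------------------------
# Spot placement and image formation
# ---------------------------------------------------------------------------

def place_spots(n: int, field_size_px: int, min_sep_px: float, border_px: float,
                rng, existing: np.ndarray | None = None) -> np.ndarray:
    """Place n spot centers uniformly at random with a minimum separation.

    Grid-accelerated dart throwing.  Raises if the field cannot accommodate
    the requested count at the required separation.
    """
    lo, hi = border_px, field_size_px - border_px
    if hi <= lo:
        raise ValueError("field too small for the requested border margin")
    cell = max(min_sep_px, 1e-9)
    n_cells = int(np.ceil((hi - lo) / cell))
    grid: dict[tuple[int, int], list[np.ndarray]] = {}

    def _cell(p):
        return (int((p[0] - lo) / cell), int((p[1] - lo) / cell))

    def _ok(p):
        cx, cy = _cell(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for q in grid.get((cx + dx, cy + dy), ()):
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < min_sep_px ** 2:
                        return False
        return True

    if existing is not None:
        for q in np.asarray(existing, dtype=float):
            grid.setdefault(_cell(q), []).append(q)

    placed: list[np.ndarray] = []
    budget = max(10_000, 400 * max(n, 1))
    attempts = 0
    while len(placed) < n:
        if attempts >= budget:
            raise ValueError(
                f"could not place {n} spots at min separation {min_sep_px:.2f} px "
                f"in a {field_size_px} px field (placed {len(placed)})")
        attempts += 1
        p = rng.uniform(lo, hi, size=2)
        if _ok(p):
            placed.append(p)
            grid.setdefault(_cell(p), []).append(p)
    return np.array(placed).reshape(n, 2)  # columns: x, y


def _add_gaussian(frame: np.ndarray, x: float, y: float, flux: float, sigma: float) -> None:
    """Add an integrated-flux Gaussian spot to a frame in place."""
    h, w = frame.shape
    r = int(np.ceil(4.0 * sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2))
    frame[y0:y1, x0:x1] += flux / (2.0 * np.pi * sigma ** 2) * g


def _apply_noise(clean: np.ndarray, preset: ConditionPreset, rng) -> np.ndarray:
    noisy = rng.poisson(clean).astype(float) if preset.noise.shot_noise else clean
    if preset.noise.read_sigma > 0:
        noisy = noisy + rng.normal(0.0, preset.noise.read_sigma, size=clean.shape)
    return noisy


def render_movie(preset: ConditionPreset, rng=None, *,
                 n_docked_exact: int | None = None,
                 n_events_exact: int | None = None) -> tuple[Movie, GroundTruth]:
    """Render one field of view as a movie plus its ground-truth sidecar.

    Docked spots are placed uniformly at random with a minimum center
    separation of ``min_sep_factor * psf_sigma_px``; each spot is an isotropic
    Gaussian whose amplitude scales with its multiplicity k and follows its
    content-dye trace over time.  The realized spot count is Poisson with mean
    ``preset.n_docked`` and each spot fuses independently with probability
    ``preset.p_fusion`` unless exact counts are requested (``n_docked_exact``
    / ``n_events_exact``), which the seeded test fixtures use to plant known
    totals.  Very large aggregates are a separate rare process, rendered
    wider and brighter than any k <= 6 cluster.
    """
    rng = _as_rng(rng, preset)
    opt = preset.optics
    n = int(rng.poisson(preset.n_docked)) if n_docked_exact is None else int(n_docked_exact)
    min_sep = opt.min_sep_factor * opt.psf_sigma_px
    centers = place_spots(n, opt.field_size_px, min_sep, opt.border_px, rng)

    ks = np.array([1] * n, dtype=int)
    if preset.cluster_size_law != {1: 1.0} and n > 0:
        kk = np.array(sorted(preset.cluster_size_law))
        pp = np.array([preset.cluster_size_law[k] for k in kk])
        ks = rng.choice(kk, size=n, p=pp)

    if n_events_exact is None:
        fused = rng.random(n) < preset.p_fusion
    else:
        if n_events_exact > n:
            raise ValueError("cannot plant more events than docked spots")
        fused = np.zeros(n, dtype=bool)
        fused[rng.choice(n, size=int(n_events_exact), replace=False)] = True
    n_fused = int(fused.sum())
    times = sample_event_times(preset, n_fused, rng) if n_fused else np.empty(0)

    truth = GroundTruth(preset_name=preset.name)
    fluxes = np.empty((n, opt.n_frames))
    it = iter(times)
    for i in range(n):
        t_ev = float(next(it)) if fused[i] else None
        fluxes[i] = _clean_flux(preset, int(ks[i]), bool(fused[i]), t_ev)
        truth.spots.append(SpotTruth(x=float(centers[i, 0]), y=float(centers[i, 1]),
                                     k=int(ks[i]), fused=bool(fused[i]), t_event_s=t_ev,
                                     baseline=float(ks[i]) * preset.flux_per_vesicle))

    n_agg = int(rng.poisson(preset.large_aggregate_rate))
    agg_centers = place_spots(n_agg, opt.field_size_px, min_sep, opt.border_px, rng,
                              existing=centers) if n_agg else np.empty((0, 2))
    agg_flux = rng.uniform(*AGGREGATE_K_RANGE, size=n_agg) * preset.flux_per_vesicle
    for i in range(n_agg):
        truth.spots.append(SpotTruth(x=float(agg_centers[i, 0]), y=float(agg_centers[i, 1]),
                                     k=0, fused=False, t_event_s=None,
                                     baseline=float(agg_flux[i]), is_aggregate=True))

    clean = np.full((opt.n_frames, opt.field_size_px, opt.field_size_px),
                    preset.noise.background, dtype=float)
    sigma_agg = AGGREGATE_SIGMA_FACTOR * opt.psf_sigma_px
    for f in range(opt.n_frames):
        for i in range(n):
            _add_gaussian(clean[f], centers[i, 0], centers[i, 1], fluxes[i, f], opt.psf_sigma_px)
        for i in range(n_agg):
            _add_gaussian(clean[f], agg_centers[i, 0], agg_centers[i, 1], agg_flux[i], sigma_agg)

    movie = Movie(_apply_noise(clean, preset, rng), opt.frame_interval_s, opt.n_pre_frames)
    return movie, truth


def render_clustering_field(surface_preset: ConditionPreset, docked_preset: ConditionPreset,
                            rng=None) -> TwoChannelField:
    """Render one clustering-assay location: saturated DiD surface + docked DiI spots.

    Channel 1 (DiD) is the dense immobilized vesicle layer used for the
    surface-saturation/homogeneity check; channel 2 (DiI) holds the docked
    clustering spots, whose count scales with the docked preset's clustering
    efficiency.  Ground truth refers to the DiI channel.
    """
    rng = _as_rng(rng, docked_preset)
    did, _ = render_movie(surface_preset, rng)
    dii, truth = render_movie(docked_preset, rng)
    return TwoChannelField(did=did, dii=dii, truth=truth)


# ---------------------------------------------------------------------------
# Seeded fusion fixture with exact planted totals
# ---------------------------------------------------------------------------

def render_fusion_fixture(preset: ConditionPreset, rng=None) -> Iterator[tuple[Movie, GroundTruth]]:
    """Yield one (Movie, GroundTruth) per field with exact planted totals.

    The pooled docked count is ``round(n_docked * n_fields)`` split evenly
    over the fields, and the pooled event count is ``round(p_fusion * total)``
    allocated to fields by drawing the fusing spots uniformly without
    replacement from the pooled population — e.g. the no-α-Syn fusion preset
    plants exactly 166 events among exactly 2000 docked vesicles.  Fields are
    yielded one at a time so callers can stream them.
    """
    rng = _as_rng(rng, preset)
    total = round(preset.n_docked * preset.n_fields)
    n_events = round(preset.p_fusion * total)
    base, extra = divmod(total, preset.n_fields)
    per_field = [base + (1 if i < extra else 0) for i in range(preset.n_fields)]
    events_per_field = rng.multivariate_hypergeometric(per_field, n_events)
    for n_spots, n_ev in zip(per_field, events_per_field):
        yield render_movie(preset, rng, n_docked_exact=n_spots, n_events_exact=int(n_ev))
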