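"""Typed containers for microcosm experiment data.

The experimental design these containers model is a size-fractionation
microcosm study: lake water is filtered to produce three treatments —

* ``V``   (< 1.6 μm): viruses + bacteria only, predator-free;
* ``VF``  (< 5 μm, dark): viruses + bacteria + flagellate grazers;
* ``VFA`` (< 5 μm, light): as VF plus small autotrophs,

each incubated in triplicate for four days with counts taken at 0, 48 and
96 h, dilution assays for viral production, and leucine-incorporation
assays for bacterial production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, ParameterError

TREATMENTS = ("V", "VF", "VFA")
#: Treatments whose fraction (< 5 μm) retains nanoflagellate grazers.
PREDATOR_TREATMENTS = ("VF", "VFA")
VARIABLES = ("bacteria", "viruses", "HNF", "PNF", "picocyanobacteria")

#: Leucine-to-carbon conversion constants (Simon & Azam style chain).
LEU_MOLAR_MASS = 131.2  # g mol^-1
PCT_LEU = 0.073  # fraction of leucine in cell protein
C_TO_PROTEIN = 0.86  # cellular carbon : protein ratio
ISOTOPE_DILUTION = 1.0

DEFAULT_BURST_SIZE = 27.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class AbundanceSeries:
    """One variable's count trajectory for one experiment/treatment/replicate.

    Times are in hours; counts in cells (or particles) per ml and must be
    strictly positive. Time zero must be present so growth-rate log ratios
    are anchored at the start of incubation.
    """

    experiment: str
    treatment: str
    replicate: int
    variable: str
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        counts = _as_float_array(self.counts, "counts")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if self.treatment not in TREATMENTS:
            raise InputError(f"unknown treatment {self.treatment!r}")
        if times.size != counts.size:
            raise InputError("times and counts must have equal length")
        if times.size == 0:
            raise InputError("empty series")
        if np.any(np.diff(times) <= 0):
            raise InputError("times must be strictly increasing")
        if times[0] != 0:
            raise InputError("series must include time 0")
        if np.any(counts <= 0):
            raise InputError("counts must be strictly positive")

    def at(self, t: float) -> float:
        """Count at time ``t`` (hours); raises if ``t`` was not sampled."""
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise InputError(
                f"time {t} h not sampled in series "
                f"{self.experiment}/{self.treatment}/{self.variable}"
            )
        return float(self.counts[idx[0]])


@dataclass(frozen=True)
class DilutionAssay:
    """A 0–24 h viral-production dilution assay.

    Hosts are diluted into virus-free water (concentration ``b`` per ml,
    down from ``B`` before dilution) and viral counts are followed over
    24 h; the regression slope of counts vs time, corrected for host
    dilution, estimates viral production.
    """

    experiment: str
    treatment: str
    replicate: int
    times: np.ndarray
    viral_counts: np.ndarray
    b: float  # bacterial concentration after dilution (ml^-1)
    B: float  # bacterial concentration before dilution (ml^-1)
    day: int = 0
    true_slope: float | None = None  # populated by the simulator only

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        counts = _as_float_array(self.viral_counts, "viral_counts")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "viral_counts", counts)
        if times.size != counts.size:
            raise InputError("times and viral_counts must have equal length")
        if times.size < 3:
            raise InputError("dilution assay needs at least 3 time points")
        if np.any(np.diff(times) <= 0):
            raise InputError("times must be strictly increasing")
        if times[0] < 0 or times[-1] > 24:
            raise InputError("dilution assay times must lie within [0, 24] h")
        if not (0 < self.b <= self.B):
            raise InputError("need 0 < b <= B for the dilution correction")


@dataclass(frozen=True)
class LeucineAssay:
    """³H-leucine incorporation measurements with killed controls.

    ``live`` and ``controls`` are incorporation rates in pmol l⁻¹ h⁻¹;
    controls are formaldehyde-killed blanks whose mean is subtracted.
    """

    experiment: str
    treatment: str
    replicate: int
    time_h: float
    live: np.ndarray
    controls: np.ndarray

    def __post_init__(self):
        live = _as_float_array(self.live, "live")
        controls = _as_float_array(self.controls, "controls")
        object.__setattr__(self, "live", live)
        object.__setattr__(self, "controls", controls)
        if live.size < 1:
            raise InputError("need at least one live measurement")
        if controls.size < 1:
            raise InputError("need at least one killed control")


@dataclass(frozen=True)
class RateRecord:
    """Growth/loss summary for one experiment × treatment × horizon.

    ``rb`` is the net growth rate in the predator treatment, ``r`` the net
    rate in the predator-free V treatment and ``g = r − rb`` the
    predator-attributable loss rate; negative ``g`` means predators
    enhanced net bacterial growth. All rates are d⁻¹.
    """

    experiment: str
    treatment: str
    horizon_h: float
    rb_mean: float
    rb_sd: float
    r_mean: float
    r_sd: float
    g_mean: float
    g_sd: float


@dataclass(frozen=True)
class LysisResult:
    """Viral production and derived lysis quantities for one assay."""

    slope: float  # m, virus ml^-1 h^-1
    vp: float  # viral production, virus ml^-1 h^-1
    lysed: float | None = None  # cell ml^-1 d^-1
    mortality: float | None = None  # d^-1
    burst_size: float = DEFAULT_BURST_SIZE
    negative_slope: bool = False


@dataclass
class BandMatrix:
    """Aligned DGGE band positions × lanes with peak-surface intensities.

    ``intensity[i, j]`` is the peak surface n_i of band ``j`` in lane
    ``i`` (0 = absent). Relative intensities P_i = n_i / N are computed
    per lane over its present bands and sum to 1.
    """

    lanes: list[str]
    positions: np.ndarray  # canonical band positions, pixels, increasing
    intensity: np.ndarray  # shape (n_lanes, n_bands)

    def __post_init__(self):
        self.positions = _as_float_array(self.positions, "positions")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.lanes), self.positions.size):
            raise InputError("intensity shape must be (n_lanes, n_bands)")
        if np.any(self.intensity < 0):
            raise InputError("band surfaces must be non-negative")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise InputError("band positions must be strictly increasing")
        if np.any(self.intensity.sum(axis=1) <= 0):
            raise InputError("every lane needs at least one band")

    @property
    def relative_intensity(self) -> np.ndarray:
        """Per-lane relative intensities P_i = n_i / N (rows sum to 1)."""
        totals = self.intensity.sum(axis=1, keepdims=True)
        return self.intensity / totals

    def lane_profile(self, lane: str) -> np.ndarray:
        return self.relative_intensity[self.lanes.index(lane)]


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters for the synthetic microcosm generator.

    Rates are per day. ``mu_b`` is the intrinsic bacterial growth rate;
    ``delta_v`` the per-capita lysis rate; ``graze`` the per-capita
    grazing loss (applied only when flagellates are present);
    ``burst_size`` the number of viruses released per lysed cell;
    ``enrich`` a multiplicative growth boost from predator-mediated
    nutrient release (VF and VFA); ``autotroph_boost`` an additional
    boost in VFA only; ``decay_v`` the viral decay rate; ``cv_noise``
    the coefficient of variation of multiplicative lognormal
    observation noise.
    """

    mu_b: float = 0.8
    delta_v: float = 0.2
    graze: float = 0.2
    burst_size: float = DEFAULT_BURST_SIZE
    enrich: float = 0.3
    autotroph_boost: float = 0.1
    decay_v: float = 0.0
    cv_noise: float = 0.05
    seed: int = 0
    bacteria0: float = 2.5e6
    viruses0: float = 1.0e8
    hnf0: float = 4.0e2
    pnf0: float = 3.0e2
    picocyano0: float = 7.0e4
    #: fraction of flagellates/picocyanobacteria surviving the 1.6-μm
    #: filtration into the V treatment (paper range: 1–5% of in situ)
    residual_fraction: float = 0.03

    def __post_init__(self):
        for name in ("mu_b", "delta_v", "graze", "enrich",
                     "autotroph_boost", "decay_v"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.burst_size <= 0:
            raise ParameterError("burst_size must be > 0")
        if not (0 <= self.cv_noise < 1):
            raise ParameterError("cv_noise must lie in [0, 1)")
        if not (0 < self.residual_fraction <= 0.05):
            raise ParameterError("residual_fraction must lie in (0, 0.05]")
        for name in ("bacteria0", "viruses0", "hnf0", "pnf0", "picocyano0"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    def net_bacterial_rate(self, treatment: str) -> float:
        """Composite net bacterial growth rate (d⁻¹) in a treatment."""
        if treatment not in TREATMENTS:
            raise ParameterError(f"unknown treatment {treatment!r}")
        boost = 0.0
        graze = 0.0
        if treatment in PREDATOR_TREATMENTS:
            boost = self.enrich
            graze = self.graze
        if treatment == "VFA":
            boost += self.autotroph_boost
        return self.mu_b * (1.0 + boost) - self.delta_v - graze


@dataclass
class ExperimentBundle:
    """All data for one microcosm experiment (e.g. LA1).

    ``truth`` carries the generator parameters for synthetic bundles and
    is absent (None) for real data.
    """

    label: str
    replicates: int
    series: list[AbundanceSeries] = field(default_factory=list)
    dilution_assays: list[DilutionAssay] = field(default_factory=list)
    leucine_assays: list[LeucineAssay] = field(default_factory=list)
    band_matrix: BandMatrix | None = None
    truth: SimulationParams | None = None

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(t for t in TREATMENTS
                     if any(s.treatment == t for s in self.series))

    def get_series(self, treatment: str, variable: str,
                   replicate: int | None = None) -> list[AbundanceSeries]:
        out = [s for s in self.series
               if s.treatment == treatment and s.variable == variable
               and (replicate is None or s.replicate == replicate)]
        return out


@dataclass(frozen=True)
class StimulationResult:
    """Stimulation (percentage points) of one quantity in one window."""

    experiment: str
    quantity: str
    treatment: str
    window: tuple[float, float]
    stimulation: float
    per_replicate: tuple[float, ...] = ()


@dataclass(frozen=True)
class ComparisonResult:
    """An ANOVA F or t comparison with its p-value."""

    statistic: float
    p_value: float
    n: int
    kind: str  # "anova", "paired_t", ...
    significant: bool
    posthoc: Mapping[tuple[str, str], float] | None = None
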