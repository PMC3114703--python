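"""Synthetic microcosm generator with known ground truth.

Every downstream estimator in this toolkit (rate kinetics, dilution-assay
viral production, leucine conversion, stimulation, fingerprint analytics)
can be exercised against data whose generating parameters are known. The
generator follows the bottle dynamics the estimators assume:

* bacteria grow/decline exponentially with a constant composite net rate
  ``mu_b·(1+boosts) − delta_v − graze`` (grazing and the enrichment boost
  act only where flagellates are present, the autotroph boost only in the
  lit VFA treatment);
* viruses gain ``burst_size`` particles per lysed cell and decay at
  ``decay_v``;
* nanoflagellates follow logistic growth where present;
  picocyanobacteria grow logistically in the light (VFA), decline slowly
  in the dark (VF) and persist as a small filtration residual in V.

Mean trajectories are deterministic ODE solutions integrated with a
fixed-step RK4; stochasticity enters only as multiplicative lognormal
observation noise (mean-preserving, CV = ``cv_noise``), so simulated
counts stay positive. Demographic (birth–death) noise is out of scope.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datatypes import (AbundanceSeries, BandMatrix, DilutionAssay,
                        ExperimentBundle, LeucineAssay, SimulationParams,
                        PREDATOR_TREATMENTS, TREATMENTS)
from .errors import InputError, ParameterError
from .production import carbon_to_leucine

RK4_STEP_H = 0.1
#: logistic rates (d⁻¹) and carrying-capacity multiples for the
#: accessory populations; roughly a doubling-to-tripling over 4 days,
#: matching the field behaviour of nanoflagellates in these bottles
FLAGELLATE_RATE = 0.35
FLAGELLATE_K_MULT = 4.0
PICO_LIGHT_RATE = 0.25
PICO_DARK_RATE = -0.2

STATE_VARS = ("bacteria", "viruses", "HNF", "PNF", "picocyanobacteria")
DILUTION_TIMES_H = (0.0, 3.0, 6.0, 12.0, 18.0, 24.0)


def _check_times(times: Sequence[float]) -> np.ndarray:
    arr = np.asarray(times, dtype=float)
    if arr.size == 0 or np.any(np.diff(arr) <= 0):
        raise InputError("times must be non-empty and strictly increasing")
    if arr[0] != 0:
        raise InputError("times must start at 0")
    return arr


def _initial_state(params: SimulationParams, treatment: str) -> np.ndarray:
    res = params.residual_fraction if treatment == "V" else 1.0
    return np.array([
        params.bacteria0,
        params.viruses0,
        params.hnf0 * res,
        params.pnf0 * res,
        params.picocyano0 * res,
    ])


def _derivative(params: SimulationParams, treatment: str,
                state: np.ndarray, k_flag: np.ndarray) -> np.ndarray:
    """Right-hand side in per-hour units (rates stored per day)."""
    b, v, hnf, pnf, pico = state
    net_b = params.net_bacterial_rate(treatment)
    db = net_b * b
    dv = params.burst_size * params.delta_v * b - params.decay_v * v
    flag_present = treatment in PREDATOR_TREATMENTS
    dhnf = FLAGELLATE_RATE * hnf * (1 - hnf / k_flag[0]) if flag_present else 0.0
    dpnf = FLAGELLATE_RATE * pnf * (1 - pnf / k_flag[1]) if flag_present else 0.0
    if treatment == "VFA":
        dpico = PICO_LIGHT_RATE * pico * (1 - pico / k_flag[2])
    elif treatment == "VF":
        dpico = PICO_DARK_RATE * pico
    else:
        dpico = 0.0
    return np.array([db, dv, dhnf, dpnf, dpico]) / 24.0


def mean_trajectory(params: SimulationParams, treatment: str,
                    times: Sequence[float],
                    step_h: float = RK4_STEP_H) -> np.ndarray:
    """Deterministic mean counts, shape (len(times), 5), RK4 fixed step."""
    if treatment not in TREATMENTS:
        raise ParameterError(f"unknown treatment {treatment!r}")
    t_grid = _check_times(times)
    state = _initial_state(params, treatment)
    k_flag = np.array([params.hnf0 * FLAGELLATE_K_MULT,
                       params.pnf0 * FLAGELLATE_K_MULT,
                       params.picocyano0 * FLAGELLATE_K_MULT])
    out = np.empty((t_grid.size, state.size))
    out[0] = state
    t = 0.0
    for i, t_target in enumerate(t_grid[1:], start=1):
        while t < t_target - 1e-12:
            h = min(step_h, t_target - t)
            k1 = _derivative(params, treatment, state, k_flag)
            k2 = _derivative(params, treatment, state + 0.5 * h * k1, k_flag)
            k3 = _derivative(params, treatment, state + 0.5 * h * k2, k_flag)
            k4 = _derivative(params, treatment, state + h * k3, k_flag)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i] = state
    return out


def _noise_factors(rng: np.random.Generator, cv: float,
                   shape) -> np.ndarray:
    """Mean-preserving lognormal factors with the requested CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def _rng_for(params: SimulationParams, treatment: str,
             replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        [params.seed, TREATMENTS.index(treatment), replicate])


def simulate_microcosm(params: SimulationParams, treatment: str,
                       times: Sequence[float], replicate: int = 0,
                       experiment: str = "SIM",
                       rng: np.random.Generator | None = None
                       ) -> dict[str, AbundanceSeries]:
    """Simulate one bottle: all five variables observed at ``times``.

    Deterministic given (seed, treatment, replicate); observation noise
    multiplies each count by an independent lognormal factor.
    """
    traj = mean_trajectory(params, treatment, times)
    rng = rng or _rng_for(params, treatment, replicate)
    noisy = traj * _noise_factors(rng, params.cv_noise, traj.shape)
    out = {}
    for j, var in enumerate(STATE_VARS):
        out[var] = AbundanceSeries(
            experiment=experiment, treatment=treatment, replicate=replicate,
            variable=var, times=np.asarray(times, dtype=float),
            counts=np.maximum(noisy[:, j], 1e-12),
        )
    return out


def simulate_dilution_assay(params: SimulationParams,
                            state: Mapping[str, float],
                            dilution_factor: float = 1.0 / 3.0,
                            times: Sequence[float] = DILUTION_TIMES_H,
                            seed: int = 0, experiment: str = "SIM",
                            treatment: str = "V", replicate: int = 0,
                            day: int = 0) -> DilutionAssay:
    """Simulate a 0–24 h viral-production dilution assay.

    ``state`` holds the bottle abundances at assay start (needs
    ``bacteria`` and ``viruses``). Hosts and viruses are both diluted by
    ``dilution_factor`` (e.g. 50 ml sample into 100 ml virus-free water
    → 1/3); mean viral counts then rise linearly at
    ``burst_size·delta_v·b/24`` per hour. The true slope is recorded for
    parameter-recovery tests.
    """
    if not (0 < dilution_factor < 1):
        raise InputError("dilution_factor must lie in (0, 1)")
    t = np.asarray(times, dtype=float)
    if t.size < 3 or np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > 24:
        raise InputError("assay times must be >=3 increasing points in [0, 24]")
    big_b = float(state["bacteria"])
    v0 = float(state["viruses"]) * dilution_factor
    b = big_b * dilution_factor
    true_slope = params.burst_size * params.delta_v * b / 24.0
    mean_counts = v0 + true_slope * t
    rng = np.random.default_rng([seed, 104729])
    counts = mean_counts * _noise_factors(rng, params.cv_noise, t.shape)
    return DilutionAssay(
        experiment=experiment, treatment=treatment, replicate=replicate,
        times=t, viral_counts=np.maximum(counts, 1e-12), b=b, B=big_b,
        day=day, true_slope=true_slope,
    )


def simulate_leucine_assay(bp_target: float, cv: float = 0.05,
                           seed: int = 0, control_level: float = 20.0,
                           n_live: int = 3, n_controls: int = 2,
                           experiment: str = "SIM", treatment: str = "V",
                           replicate: int = 0,
                           time_h: float = 0.0) -> LeucineAssay:
    """Leucine assay whose blank-corrected mean maps back to ``bp_target``.

    ``bp_target`` is the intended bacterial production in μgC l⁻¹ h⁻¹;
    live tubes receive the matching net leucine rate plus the control
    background, each perturbed by lognormal noise.
    """
    if bp_target < 0:
        raise InputError("bp_target must be >= 0")
    net_leu = carbon_to_leucine(bp_target)
    rng = np.random.default_rng([seed, 224737])
    live = ((net_leu + control_level)
            * _noise_factors(rng, cv, n_live))
    controls = control_level * _noise_factors(rng, cv, n_controls)
    return LeucineAssay(experiment=experiment, treatment=treatment,
                        replicate=replicate, time_h=time_h,
                        live=live, controls=controls)


# ---------------------------------------------------------------------------
# gel fingerprint simulation

def _canonical_positions(n_phylotypes: int, base: float = 100.0,
                         spacing: float = 10.0) -> np.ndarray:
    return base + spacing * np.arange(n_phylotypes)


def simulate_lane_bands(profiles: Mapping[str, Sequence[float]],
                        detection_floor: float = 0.004,
                        position_jitter: float = 0.0, seed: int = 0,
                        total_surface: float = 1000.0
                        ) -> dict[str, list[tuple[float, float]]]:
    """Per-lane (position, surface) band lists with per-lane jitter.

    Each lane's profile is a vector of phylotype relative abundances
    summing to 1; phylotypes below ``detection_floor`` yield no band.
    Suitable as input to :func:`microloop.fingerprint.match_bands`.
    """
    rng = np.random.default_rng([seed, 611953])
    lanes = {}
    n = None
    for lane, profile in profiles.items():
        p = np.asarray(profile, dtype=float)
        if n is None:
            n = p.size
        elif p.size != n:
            raise InputError("all lanes must cover the same phylotype set")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise InputError(f"lane {lane!r} profile is not normalized")
        positions = _canonical_positions(n)
        bands = []
        for pos, abundance in zip(positions, p):
            if abundance >= detection_floor:
                jitter = rng.normal(0.0, position_jitter) \
                    if position_jitter > 0 else 0.0
                bands.append((pos + jitter, abundance * total_surface))
        lanes[lane] = bands
    return lanes


def simulate_gel(profiles: Mapping[str, Sequence[float]],
                 detection_floor: float = 0.004,
                 position_jitter: float = 0.0, seed: int = 0,
                 total_surface: float = 1000.0) -> BandMatrix:
    """Simulate a quantified gel as an aligned band matrix.

    Bands are aligned at their canonical (truth) positions; the jitter
    requested is reflected in the canonical position only through its
    per-band mean across lanes, mirroring what alignment against a
    reference pattern achieves.
    """
    raw = simulate_lane_bands(profiles, detection_floor, position_jitter,
                              seed, total_surface)
    n = len(next(iter(profiles.values())))
    canonical = _canonical_positions(n)
    lanes = list(profiles)
    intensity = np.zeros((len(lanes), n))
    observed_pos = [[] for _ in range(n)]
    for i, lane in enumerate(lanes):
        for pos, surface in raw[lane]:
            j = int(np.argmin(np.abs(canonical - pos)))
            intensity[i, j] += surface
            observed_pos[j].append(pos)
    present = intensity.sum(axis=0) > 0
    positions = np.array([
        np.mean(observed_pos[j]) if observed_pos[j] else canonical[j]
        for j in range(n)
    ])
    order = np.argsort(positions[present])
    return BandMatrix(lanes=lanes,
                      positions=positions[present][order],
                      intensity=intensity[:, present][:, order])


def partition_profiles(tallies: Mapping[str, int],
                       treatments: Sequence[str] = TREATMENTS
                       ) -> dict[str, np.ndarray]:
    """Equal-abundance lane profiles realizing a band-sharing partition.

    ``tallies`` gives the total band count and the sizes of the sharing
    classes (``common``, single-treatment specifics ``V``/``VF``/``VFA``
    and the pair class ``"VFA+VF"``); any remainder is split between the
    V+VF and V+VFA pair classes so the partition identity
    (common + specifics + two-way classes = total) holds.
    """
    total = tallies["total"]
    classes = []
    classes += [("V", "VF", "VFA")] * tallies.get("common", 0)
    classes += [("V",)] * tallies.get("V", 0)
    classes += [("VF",)] * tallies.get("VF", 0)
    classes += [("VFA",)] * tallies.get("VFA", 0)
    classes += [("VF", "VFA")] * tallies.get("VFA+VF", 0)
    remainder = total - len(classes)
    if remainder < 0:
        raise InputError("band classes exceed the stated total")
    classes += [("V", "VF")] * ((remainder + 1) // 2)
    classes += [("V", "VFA")] * (remainder // 2)
    profiles = {}
    for treatment in treatments:
        mask = np.array([treatment in members for members in classes],
                        dtype=float)
        if mask.sum() == 0:
            raise InputError(f"treatment {treatment!r} has no bands")
        profiles[treatment] = mask / mask.sum()
    return profiles


# ---------------------------------------------------------------------------
# full experiment bundles

def make_bundle(params: SimulationParams,
                treatments: Iterable[str] = TREATMENTS,
                replicates: int = 3,
                times: Sequence[float] = (0.0, 48.0, 96.0),
                assay_days: Sequence[int] = (0, 2, 4),
                label: str = "SIM",
                band_tallies: Mapping[str, int] | None = None,
                bp_scale: float = 2.0e-6) -> ExperimentBundle:
    """Simulate a complete experiment: counts, assays and (optionally) a gel.

    ``bp_scale`` converts bacterial abundance (cell ml⁻¹) to a bacterial
    production target (μgC l⁻¹ h⁻¹); the default puts preset scenarios in
    the observed field span of roughly 0.5–8 μgC l⁻¹ h⁻¹.
    """
    bundle = ExperimentBundle(label=label, replicates=replicates,
                              truth=params)
    for treatment in treatments:
        mean_traj = mean_trajectory(params, treatment, times)
        for rep in range(replicates):
            series = simulate_microcosm(params, treatment, times,
                                        replicate=rep, experiment=label)
            bundle.series.extend(series.values())
            for day in assay_days:
                t_h = 24.0 * day
                idx = int(np.argmin(np.abs(np.asarray(times) - t_h)))
                state = dict(zip(STATE_VARS, mean_traj[idx]))
                assay_seed = (params.seed * 1000003
                              + TREATMENTS.index(treatment) * 9176
                              + rep * 131 + day) % (2 ** 31)
                bundle.dilution_assays.append(simulate_dilution_assay(
                    params, state, seed=assay_seed, experiment=label,
                    treatment=treatment, replicate=rep, day=day))
                bp_target = bp_scale * state["bacteria"]
                bundle.leucine_assays.append(simulate_leucine_assay(
                    bp_target, cv=params.cv_noise, seed=assay_seed,
                    experiment=label, treatment=treatment, replicate=rep,
                    time_h=t_h))
    if band_tallies is not None:
        profiles = partition_profiles(band_tallies)
        bundle.band_matrix = simulate_gel(profiles, seed=params.seed)
    return bundle


def enrich_for_stimulation(target_pct: float, v_net_rate: float,
                           window_h: float = 48.0) -> float:
    """Net-rate increment producing an exact abundance stimulation.

    Under exponential dynamics the stimulation of abundance over a
    window T is 100·(e^{r_T·T} − e^{r_V·T}); this returns the treated
    net rate r_T (d⁻¹) achieving ``target_pct`` percentage points over
    ``window_h`` hours given the V net rate.
    """
    t_days = window_h / 24.0
    inner = math.exp(v_net_rate * t_days) + target_pct / 100.0
    if inner <= 0:
        raise ParameterError("target stimulation unreachable")
    return math.log(inner) / t_days
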