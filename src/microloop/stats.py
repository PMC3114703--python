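"""Predator-stimulation statistic and the supporting comparisons.

The stimulation of a quantity X in a predator treatment T (VF or VFA)
relative to the predator-free V treatment over a window [t0, t1] is the
difference of relative variations, in percentage points:

    S = 100 × [ (X_T(t1) − X_T(t0)) / X_T(t0)
                − (X_V(t1) − X_V(t0)) / X_V(t0) ]

Positive S means the predator treatment increased more (or decreased
less) than V. Treatment comparisons use one-way ANOVA with Fisher's
protected LSD post hoc (pairwise tests only when the omnibus F is
significant) and paired t tests for lake/season contrasts, all at
α = 0.05.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (AbundanceSeries, ComparisonResult, ExperimentBundle,
                        StimulationResult)
from .errors import DegenerateDataError, InputError

ALPHA = 0.05
WINDOWS_H = ((0.0, 48.0), (48.0, 96.0), (0.0, 96.0))
MODES = ("relative", "absolute")


def stimulation_from_values(xt0: float, xt1: float, xv0: float, xv1: float,
                            mode: str = "relative") -> float:
    """Stimulation from the four endpoint values.

    ``relative`` is the standard definition above; ``absolute`` is a
    sensitivity variant using absolute differences scaled by the V
    baseline.
    """
    if mode not in MODES:
        raise InputError(f"unknown stimulation mode {mode!r}")
    if xt0 == 0 or xv0 == 0:
        raise InputError("zero value at window start")
    if mode == "relative":
        return 100.0 * ((xt1 - xt0) / xt0 - (xv1 - xv0) / xv0)
    return 100.0 * ((xt1 - xt0) - (xv1 - xv0)) / xv0


def stimulation(treated: AbundanceSeries, reference: AbundanceSeries,
                t_start: float, t_end: float,
                mode: str = "relative") -> float:
    """Stimulation of ``treated`` (VF/VFA) against ``reference`` (V)."""
    if t_end <= t_start:
        raise InputError("t_end must exceed t_start")
    return stimulation_from_values(
        treated.at(t_start), treated.at(t_end),
        reference.at(t_start), reference.at(t_end), mode=mode)


def stimulation_replicates(bundle: ExperimentBundle, treatment: str,
                           window: tuple[float, float],
                           variable: str = "bacteria",
                           mode: str = "relative") -> StimulationResult:
    """Per-replicate stimulation against the replicate-mean V trajectory.

    V and predator bottles are physically distinct, so each predator
    replicate is compared with the mean V relative change.
    """
    t0, t1 = window
    v_series = bundle.get_series("V", variable)
    if not v_series:
        raise InputError(f"bundle {bundle.label} lacks a V treatment")
    v_rel = np.mean([(s.at(t1) - s.at(t0)) / s.at(t0) for s in v_series])
    values = []
    for s in bundle.get_series(treatment, variable):
        rel = (s.at(t1) - s.at(t0)) / s.at(t0)
        values.append(100.0 * (rel - v_rel))
    if not values:
        raise InputError(f"bundle {bundle.label} lacks treatment {treatment}")
    return StimulationResult(
        experiment=bundle.label, quantity=variable, treatment=treatment,
        window=window, stimulation=float(np.mean(values)),
        per_replicate=tuple(values))


def one_way_anova(groups: Sequence[Sequence[float]],
                  labels: Sequence[str] | None = None,
                  alpha: float = ALPHA) -> ComparisonResult:
    """One-way F test with Fisher's protected LSD post hoc.

    Pairwise LSD p-values (pooled within-group MSE, df = N − k) are
    attached only when the omnibus F is significant at ``alpha``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InputError("need >=2 groups with >=2 values each")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0 and ssb == 0:
        f_stat, p = 0.0, 1.0
    elif ssw == 0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    significant = p < alpha
    posthoc = None
    if significant and ssw > 0:
        labels = list(labels) if labels is not None \
            else [str(i) for i in range(k)]
        mse = ssw / df_w
        posthoc = {}
        for (i, a), (j, b) in itertools.combinations(enumerate(arrays), 2):
            se = math.sqrt(mse * (1 / a.size + 1 / b.size))
            t = (a.mean() - b.mean()) / se
            posthoc[(labels[i], labels[j])] = float(
                2 * sps.t.sf(abs(t), df_w))
    return ComparisonResult(statistic=float(f_stat), p_value=float(p),
                            n=n_total, kind="anova",
                            significant=significant, posthoc=posthoc)


def paired_t(x: Sequence[float], y: Sequence[float],
             alpha: float = ALPHA) -> ComparisonResult:
    """Classical two-sided paired t test on the differences x − y."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise InputError("paired samples must have equal length")
    if xa.size < 2:
        raise InputError("need at least 2 pairs")
    d = xa - ya
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return ComparisonResult(statistic=0.0, p_value=1.0, n=xa.size,
                                    kind="paired_t", significant=False)
        raise DegenerateDataError(
            "constant nonzero paired difference: t undefined")
    t_stat, p = sps.ttest_rel(xa, ya)
    return ComparisonResult(statistic=float(t_stat), p_value=float(p),
                            n=xa.size, kind="paired_t",
                            significant=bool(p < alpha))


def _lake(label: str) -> str:
    return label[:2]


def _season(label: str) -> str:
    return "spring" if label.endswith("1") else "summer"


def summarize_stimulation(bundles: Iterable[ExperimentBundle],
                          variable: str = "bacteria",
                          treatments: Sequence[str] = ("VF", "VFA"),
                          windows: Sequence[tuple[float, float]] = WINDOWS_H,
                          mode: str = "relative"
                          ) -> tuple[pd.DataFrame, dict[str, ComparisonResult]]:
    """Stimulation table by experiment × treatment × window plus contrasts.

    Returns the long-format table (with per-replicate values expanded)
    and, where both levels are present, paired t contrasts between lakes
    (LA vs LB) and between seasons (spring vs summer), pairing replicate
    stimulation values across the factor being contrasted.
    """
    rows = []
    for bundle in bundles:
        for treatment in treatments:
            if treatment not in bundle.treatments:
                continue
            for window in windows:
                res = stimulation_replicates(bundle, treatment, window,
                                             variable, mode)
                for rep, value in enumerate(res.per_replicate):
                    rows.append({
                        "experiment": bundle.label,
                        "lake": _lake(bundle.label),
                        "season": _season(bundle.label),
                        "treatment": treatment,
                        "window": f"{int(window[0])}-{int(window[1])}h",
                        "replicate": rep,
                        "stimulation_pct": value,
                    })
    table = pd.DataFrame(rows)
    contrasts: dict[str, ComparisonResult] = {}
    if not table.empty:
        for factor in ("lake", "season"):
            levels = sorted(table[factor].unique())
            if len(levels) != 2:
                continue
            others = [c for c in ("lake", "season") if c != factor]
            keys = others + ["treatment", "window", "replicate"]
            a = table[table[factor] == levels[0]].set_index(keys)
            b = table[table[factor] == levels[1]].set_index(keys)
            shared = a.index.intersection(b.index)
            if len(shared) >= 2:
                contrasts[factor] = paired_t(
                    a.loc[shared, "stimulation_pct"].to_numpy(),
                    b.loc[shared, "stimulation_pct"].to_numpy())
    return table, contrasts
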