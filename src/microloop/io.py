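"""CSV/YAML readers and writers for the pipeline's long-format files.

All tabular inputs are plain CSV with explicit headers:

* counts.csv    — experiment,treatment,replicate,variable,time_h,value
* dilution.csv  — experiment,treatment,replicate,day,time_h,viral_count,b,B
* leucine.csv   — experiment,treatment,replicate,time_h,kind,value
                  (kind ∈ {live, control})
* bands.csv     — lane,position_px,surface

Readers validate and report offending line numbers (1-based, header is
line 1).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (AbundanceSeries, DilutionAssay, ExperimentBundle,
                        LeucineAssay, SimulationParams)
from .errors import ConfigurationError, InputError

COUNTS_COLUMNS = ["experiment", "treatment", "replicate", "variable",
                  "time_h", "value"]
DILUTION_COLUMNS = ["experiment", "treatment", "replicate", "day",
                    "time_h", "viral_count", "b", "B"]
LEUCINE_COLUMNS = ["experiment", "treatment", "replicate", "time_h",
                   "kind", "value"]
BANDS_COLUMNS = ["lane", "position_px", "surface"]


def _read_table(path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != list(columns):
        raise InputError(
            f"{path}: malformed header {list(df.columns)}, "
            f"expected {list(columns)}")
    return df


def read_counts(path) -> list[AbundanceSeries]:
    """Read a long-format counts file into validated series."""
    df = _read_table(path, COUNTS_COLUMNS)
    bad = df.index[df.value <= 0]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise InputError(f"{path}: non-positive counts at line(s) {lines}")
    keys = ["experiment", "treatment", "replicate", "variable", "time_h"]
    dup = df.index[df.duplicated(subset=keys)]
    if len(dup):
        raise InputError(
            f"{path}: duplicate (series, time) row at line {dup[0] + 2}")
    out = []
    group_keys = ["experiment", "treatment", "replicate", "variable"]
    for (exp, trt, rep, var), grp in df.groupby(group_keys, sort=True):
        grp = grp.sort_values("time_h")
        out.append(AbundanceSeries(
            experiment=str(exp), treatment=str(trt), replicate=int(rep),
            variable=str(var), times=grp.time_h.to_numpy(),
            counts=grp.value.to_numpy()))
    return out


def write_counts(series: Sequence[AbundanceSeries], path) -> None:
    rows = [
        {"experiment": s.experiment, "treatment": s.treatment,
         "replicate": s.replicate, "variable": s.variable,
         "time_h": t, "value": c}
        for s in series for t, c in zip(s.times, s.counts)
    ]
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, index=False)


def read_dilution(path) -> list[DilutionAssay]:
    df = _read_table(path, DILUTION_COLUMNS)
    out = []
    keys = ["experiment", "treatment", "replicate", "day"]
    for (exp, trt, rep, day), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        b = grp.b.iloc[0]
        big_b = grp.B.iloc[0]
        out.append(DilutionAssay(
            experiment=str(exp), treatment=str(trt), replicate=int(rep),
            times=grp.time_h.to_numpy(),
            viral_counts=grp.viral_count.to_numpy(),
            b=float(b), B=float(big_b), day=int(day)))
    return out


def write_dilution(assays: Sequence[DilutionAssay], path) -> None:
    rows = [
        {"experiment": a.experiment, "treatment": a.treatment,
         "replicate": a.replicate, "day": a.day, "time_h": t,
         "viral_count": c, "b": a.b, "B": a.B}
        for a in assays for t, c in zip(a.times, a.viral_counts)
    ]
    pd.DataFrame(rows, columns=DILUTION_COLUMNS).to_csv(path, index=False)


def read_leucine(path) -> list[LeucineAssay]:
    df = _read_table(path, LEUCINE_COLUMNS)
    bad = df.index[~df.kind.isin(["live", "control"])]
    if len(bad):
        raise InputError(f"{path}: unknown kind at line {bad[0] + 2}")
    out = []
    keys = ["experiment", "treatment", "replicate", "time_h"]
    for (exp, trt, rep, t), grp in df.groupby(keys, sort=True):
        out.append(LeucineAssay(
            experiment=str(exp), treatment=str(trt), replicate=int(rep),
            time_h=float(t),
            live=grp[grp.kind == "live"].value.to_numpy(),
            controls=grp[grp.kind == "control"].value.to_numpy()))
    return out


def write_leucine(assays: Sequence[LeucineAssay], path) -> None:
    rows = []
    for a in assays:
        for v in a.live:
            rows.append({"experiment": a.experiment, "treatment": a.treatment,
                         "replicate": a.replicate, "time_h": a.time_h,
                         "kind": "live", "value": v})
        for v in a.controls:
            rows.append({"experiment": a.experiment, "treatment": a.treatment,
                         "replicate": a.replicate, "time_h": a.time_h,
                         "kind": "control", "value": v})
    pd.DataFrame(rows, columns=LEUCINE_COLUMNS).to_csv(path, index=False)


def read_bands(path) -> dict[str, list[tuple[float, float]]]:
    """Read a raw band list keyed by lane, for `fingerprint.match_bands`."""
    df = _read_table(path, BANDS_COLUMNS)
    bad = df.index[df.surface <= 0]
    if len(bad):
        raise InputError(f"{path}: non-positive surface at line {bad[0] + 2}")
    out: dict[str, list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.lane), []).append(
            (float(row.position_px), float(row.surface)))
    return out


def write_bands(raw_lanes: Mapping[str, Sequence[tuple[float, float]]],
                path) -> None:
    rows = [{"lane": lane, "position_px": pos, "surface": surface}
            for lane, bands in raw_lanes.items()
            for pos, surface in bands]
    pd.DataFrame(rows, columns=BANDS_COLUMNS).to_csv(path, index=False)


def write_bundle(bundle: ExperimentBundle, outdir) -> None:
    """Write a simulated bundle to a directory of CSVs plus truth.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(bundle.series, outdir / "counts.csv")
    if bundle.dilution_assays:
        write_dilution(bundle.dilution_assays, outdir / "dilution.csv")
    if bundle.leucine_assays:
        write_leucine(bundle.leucine_assays, outdir / "leucine.csv")
    if bundle.band_matrix is not None:
        raw = {
            lane: [(pos, surf) for pos, surf
                   in zip(bundle.band_matrix.positions,
                          bundle.band_matrix.intensity[i])
                   if surf > 0]
            for i, lane in enumerate(bundle.band_matrix.lanes)
        }
        write_bands(raw, outdir / "bands.csv")
    if bundle.truth is not None:
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(bundle.truth), fh,
                           sort_keys=True)


def bundles_from_series(series: Sequence[AbundanceSeries],
                        dilution: Sequence[DilutionAssay] = (),
                        leucine: Sequence[LeucineAssay] = ()
                        ) -> list[ExperimentBundle]:
    """Group flat record lists into per-experiment bundles."""
    labels = sorted({s.experiment for s in series})
    out = []
    for label in labels:
        sel = [s for s in series if s.experiment == label]
        reps = {s.replicate for s in sel}
        bundle = ExperimentBundle(label=label, replicates=len(reps))
        bundle.series = sel
        bundle.dilution_assays = [a for a in dilution
                                  if a.experiment == label]
        bundle.leucine_assays = [a for a in leucine
                                 if a.experiment == label]
        out.append(bundle)
    return out


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    counts: str | None = None
    dilution: str | None = None
    leucine: str | None = None
    bands: str | None = None
    outdir: str = "microloop_out"
    burst_size: float = 27.0
    stimulation_mode: str = "relative"
    vp_correction: str = "b_over_B"
    band_tolerance_px: float = 5.0
    detection_floor: float = 0.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.burst_size <= 0:
            raise ConfigurationError("burst_size must be > 0")
        if self.stimulation_mode not in ("relative", "absolute"):
            raise ConfigurationError("unknown stimulation_mode")
        if self.vp_correction not in ("b_over_B", "B_over_b"):
            raise ConfigurationError("unknown vp_correction")
        if self.band_tolerance_px <= 0:
            raise ConfigurationError("band_tolerance_px must be > 0")
        if not (0 <= self.detection_floor < 1):
            raise ConfigurationError("detection_floor must lie in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
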