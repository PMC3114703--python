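"""End-to-end pipeline driver: counts → rates, VP, BP, stimulation, gel.

`run_pipeline` reads the configured inputs, executes each analysis stage,
and writes one CSV per stage plus a run manifest (seed, config, package
version). Output is deterministic: two runs with the same config produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import ExperimentBundle
from .errors import MicroloopError
from .fingerprint import (cluster_lanes, commonality_table, match_bands,
                          similarity_matrix)
from .io import (PipelineConfig, bundles_from_series, read_bands,
                 read_counts, read_dilution, read_leucine)
from .kinetics import rate_table
from .production import bacterial_production
from .stats import summarize_stimulation
from .viral import analyse_assay

log = logging.getLogger("microloop")

#: lanes are named <treatment>_<time> (e.g. V_0, VF_final); treatment is
#: the prefix before the underscore
def _lane_treatment(lane: str) -> str:
    return lane.split("_")[0]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MicroloopError as exc:
                raise MicroloopError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("kinetics")
def _run_rates(bundles: list[ExperimentBundle]) -> pd.DataFrame:
    return pd.concat([rate_table(b) for b in bundles], ignore_index=True)


@_stage("viral_activity")
def _run_vp(bundles, burst_size, correction) -> pd.DataFrame:
    rows = []
    for bundle in bundles:
        for assay in bundle.dilution_assays:
            series = bundle.get_series(assay.treatment, "bacteria",
                                       assay.replicate)
            abundance = assay.B if not series else \
                series[0].at(24.0 * assay.day)
            res = analyse_assay(assay, abundance, burst_size, correction)
            rows.append({
                "experiment": assay.experiment,
                "treatment": assay.treatment,
                "replicate": assay.replicate, "day": assay.day,
                "slope": res.slope, "vp": res.vp, "lysed": res.lysed,
                "lysis_mortality": res.mortality,
            })
    return pd.DataFrame(rows)


@_stage("bacterial_production")
def _run_bp(bundles) -> pd.DataFrame:
    rows = []
    for bundle in bundles:
        for assay in bundle.leucine_assays:
            rows.append({
                "experiment": assay.experiment,
                "treatment": assay.treatment,
                "replicate": assay.replicate, "time_h": assay.time_h,
                "bp_ugc_l_h": bacterial_production(assay),
            })
    return pd.DataFrame(rows)


@_stage("stimulation")
def _run_stim(bundles, mode) -> pd.DataFrame:
    table, contrasts = summarize_stimulation(bundles, mode=mode)
    for factor, res in contrasts.items():
        log.info("%s contrast: t = %.3f, p = %.4f (n = %d)",
                 factor, res.statistic, res.p_value, res.n)
    return table


@_stage("fingerprint")
def _run_gel(raw_lanes, tolerance, floor, outdir):
    matrix = match_bands(raw_lanes, tolerance)
    lane_map = {lane: _lane_treatment(lane) for lane in matrix.lanes}
    table = commonality_table(matrix, lane_map, floor)
    sim = similarity_matrix(matrix)
    tree = cluster_lanes(matrix)
    table.to_frame().to_csv(Path(outdir) / "commonality.csv", index=False)
    sim.to_csv(Path(outdir) / "similarity.csv")
    with open(Path(outdir) / "tree.nwk", "w") as fh:
        fh.write(str(tree))


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute all configured stages; returns the tables it wrote."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    series = read_counts(config.counts) if config.counts else []
    dilution = read_dilution(config.dilution) if config.dilution else []
    leucine = read_leucine(config.leucine) if config.leucine else []
    bundles = bundles_from_series(series, dilution, leucine)

    if bundles:
        results["rates"] = _run_rates(bundles)
        results["rates"].to_csv(outdir / "rates.csv", index=False,
                                float_format="%.6g")
        if dilution:
            results["lysis"] = _run_vp(bundles, config.burst_size,
                                       config.vp_correction)
            results["lysis"].to_csv(outdir / "lysis.csv", index=False,
                                    float_format="%.6g")
        if leucine:
            results["bp"] = _run_bp(bundles)
            results["bp"].to_csv(outdir / "bp.csv", index=False,
                                 float_format="%.6g")
        results["stimulation"] = _run_stim(bundles, config.stimulation_mode)
        results["stimulation"].to_csv(outdir / "stimulation.csv",
                                      index=False, float_format="%.6g")
    if config.bands:
        raw = read_bands(config.bands)
        _run_gel(raw, config.band_tolerance_px, config.detection_floor,
                 outdir)
    else:
        log.info("no bands file configured; fingerprint stage skipped")

    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": dataclasses.asdict(config),
    }
    with open(outdir / "run.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return results
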