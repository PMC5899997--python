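"""Configuration, on-disk formats and end-to-end pipeline orchestration.

A run proceeds simulate -> analyze -> stats -> burden and writes:

* per-cohort trace directories (one TSV sweep table + JSON sidecar per cell,
  per protocol; optionally a single HDF5 container),
* ``cells.tsv`` (one row per cell: the seven parameters + QC flags),
* ``variants_summary.tsv`` (per-variant mean/SE/N),
* ``comparisons.tsv`` and ``classification.tsv``,
* ``burden.tsv``,
* ``manifest.json`` (config hash, seed, package/library versions).

Identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .burden import carrier_burden, variant_level_burden
from .calibration import population_from_summary
from .gating_model import (CellRecording, PopulationSpec, SweepRecording,
                           VoltageProtocol, build_standard_protocols,
                           generate_cohort)
from .reference_data import (N_CASES, N_CASES_US, N_CONTROLS,
                             biophysics_summary, variant_records)
from .trace_analysis import AnalysisConfig, analyze_cell, cells_to_frame, \
    summarize_variant
from .variant_stats import (classify_variant, compare_variants,
                            comparisons_to_frame)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "run_pipeline",
    "make_fixtures",
    "write_cohort",
    "read_cohort",
    "write_cohort_hdf5",
    "read_cohort_hdf5",
    "default_config",
]


class ConfigError(ValueError):
    """The run configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


# ---------------------------------------------------------------------------
# trace I/O


def write_cohort(directory: str | Path, cells: Sequence[CellRecording],
                 seed: int | None = None) -> None:
    """One TSV sweep table + JSON sidecar per cell and protocol.

    The TSV has ``time_ms`` first, then one current column (pA) per sweep;
    the sidecar carries cell metadata and the full protocol definition.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cell in cells:
        meta = {
            "cell_id": cell.cell_id,
            "variant_id": cell.variant_id,
            "capacitance_pF": cell.capacitance_pF,
            "series_resistance_MOhm": cell.series_resistance_MOhm,
            "protocols": {name: rec.protocol.to_dict()
                          for name, rec in cell.recordings.items()},
            "seed": seed,
        }
        (directory / f"{cell.cell_id}.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True))
        for name, rec in cell.recordings.items():
            df = pd.DataFrame(
                rec.data,
                columns=[f"sweep_{i:02d}" for i in range(rec.data.shape[1])])
            df.insert(0, "time_ms", rec.protocol.time_axis())
            df.to_csv(directory / f"{cell.cell_id}.{name}.tsv", sep="\t",
                      index=False, float_format="%.6g")


def read_cohort(directory: str | Path) -> list[CellRecording]:
    """Read back a trace directory written by :func:`write_cohort`."""
    directory = Path(directory)
    cells = []
    for sidecar in sorted(directory.glob("*.json")):
        meta = json.loads(sidecar.read_text())
        recs = {}
        for name, proto_dict in meta["protocols"].items():
            proto = VoltageProtocol.from_dict(proto_dict)
            df = pd.read_csv(directory / f"{meta['cell_id']}.{name}.tsv",
                             sep="\t")
            data = df.drop(columns=["time_ms"]).to_numpy(dtype=float)
            recs[name] = SweepRecording(protocol=proto, data=data)
        cells.append(CellRecording(
            cell_id=meta["cell_id"], variant_id=meta["variant_id"],
            capacitance_pF=float(meta["capacitance_pF"]),
            series_resistance_MOhm=float(meta["series_resistance_MOhm"]),
            recordings=recs))
    return cells


def write_cohort_hdf5(path: str | Path, cells: Sequence[CellRecording],
                      seed: int | None = None) -> None:
    """Single-file HDF5 container with the same layout as the TSV dialect."""
    import h5py
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        for cell in cells:
            g = f.create_group(cell.cell_id)
            g.attrs["variant_id"] = cell.variant_id
            g.attrs["capacitance_pF"] = cell.capacitance_pF
            g.attrs["series_resistance_MOhm"] = cell.series_resistance_MOhm
            for name, rec in cell.recordings.items():
                d = g.create_dataset(name, data=rec.data)
                d.attrs["protocol"] = json.dumps(rec.protocol.to_dict())


def read_cohort_hdf5(path: str | Path) -> list[CellRecording]:
    import h5py
    cells = []
    with h5py.File(path, "r") as f:
        for cell_id in sorted(f):
            g = f[cell_id]
            recs = {}
            for name in sorted(g):
                proto = VoltageProtocol.from_dict(
                    json.loads(g[name].attrs["protocol"]))
                recs[name] = SweepRecording(protocol=proto,
                                            data=g[name][()])
            cells.append(CellRecording(
                cell_id=cell_id, variant_id=str(g.attrs["variant_id"]),
                capacitance_pF=float(g.attrs["capacitance_pF"]),
                series_resistance_MOhm=float(g.attrs["series_resistance_MOhm"]),
                recordings=recs))
    return cells


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run.

    ``cohorts`` maps variant ids to summary rows (the fields of
    :func:`navclamp.reference_data.biophysics_summary`); an empty mapping is a
    valid (empty) run.  ``scale`` shrinks cohort sizes proportionally for
    quick runs.  One global ``seed`` drives all randomness through named
    streams, so adding a cohort does not perturb the draws of the others.
    """

    cohorts: list[dict] = field(default_factory=list)
    wild_type_id: str = "wild_type"
    sample_interval_ms: float = 0.02
    noise_sd_pA: float = 10.0
    scale: float = 1.0
    erev_policy: str = "per_cell"
    fixed_erev_mV: float = 65.0
    stats_method: str | None = None     # None = per-parameter defaults
    alpha: float = 0.05
    n_cases: int = N_CASES
    n_controls: int = N_CONTROLS
    seed: int = 0
    write_traces: bool = False

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if not 0 < self.scale <= 1.0:
            raise ConfigError("scale must be in (0, 1]")
        if self.stats_method not in (None, "kw_dunn", "anova_games_howell"):
            raise ConfigError(f"unknown stats method {self.stats_method!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        ids = [c.get("variant_id") for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate cohort variant ids")
        if self.cohorts and self.wild_type_id not in ids:
            raise ConfigError(f"wild-type cohort {self.wild_type_id!r} missing")
        required = {"variant_id", "N_density", "N_bio", "N_rec",
                    *_SUMMARY_FIELDS}
        for c in self.cohorts:
            missing = required - set(c)
            if missing:
                raise ConfigError(
                    f"cohort {c.get('variant_id')}: missing fields {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SUMMARY_FIELDS = ("Ipeak_density_pA_per_pF", "se_Ipeak", "act_V12_mV",
                   "se_act_V12", "act_Vslope_mV", "se_act_Vslope",
                   "inact_V12_mV", "se_inact_V12", "inact_Vslope_mV",
                   "se_inact_Vslope", "tau_inact_0mV_ms", "se_tau_inact",
                   "tau_rec_ms", "se_tau_rec")


def default_config(seed: int = 0, scale: float = 1.0,
                   write_traces: bool = False) -> RunConfig:
    """The shipped study configuration: all 15 cohorts at the printed N."""
    cohorts = biophysics_summary().to_dict(orient="records")
    cfg = RunConfig(cohorts=cohorts, seed=seed, scale=scale,
                    write_traces=write_traces)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# pipeline


def _cohort_spec(cfg: RunConfig, row: Mapping) -> PopulationSpec:
    n = max(3, round(row["N_density"] * cfg.scale))
    n_rec = max(3, round(row["N_rec"] * cfg.scale))
    protocols = build_standard_protocols(cfg.sample_interval_ms)
    analysis = AnalysisConfig(erev_policy=cfg.erev_policy,  # type: ignore[arg-type]
                              fixed_erev_mV=cfg.fixed_erev_mV)
    return population_from_summary(row, seed=cfg.seed, n_cells=n,
                                   n_recovery=n_rec,
                                   noise_sd_pA=cfg.noise_sd_pA,
                                   protocols=protocols, config=analysis)


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 log=print) -> dict[str, Path]:
    """Execute all stages and write the report bundle to ``out_dir``.

    Returns a mapping of artefact names to paths.  Any stage failure raises
    :class:`StageError` naming the stage and the cell/variant context.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocols = build_standard_protocols(config.sample_interval_ms)
    analysis = AnalysisConfig(erev_policy=config.erev_policy,  # type: ignore[arg-type]
                              fixed_erev_mV=config.fixed_erev_mV)
    warnings_log: list[str] = []

    # --- simulate + analyze -------------------------------------------------
    bio_frames = []
    for row in config.cohorts:
        vid = row["variant_id"]
        try:
            spec = _cohort_spec(config, row)
            cells, _truth = generate_cohort(spec, protocols,
                                            log=warnings_log.append)
            if config.write_traces:
                write_cohort(out / "traces" / vid, cells, seed=config.seed)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"simulate: cohort {vid}: {e}") from e
        for cell in cells:
            try:
                bio_frames.append(analyze_cell(cell, analysis))
            except Exception as e:  # noqa: BLE001
                raise StageError(f"analyze: cell {cell.cell_id}: {e}") from e
    cells_df = cells_to_frame(bio_frames)
    paths = {"cells": out / "cells.tsv"}
    cells_df.to_csv(paths["cells"], sep="\t", index=False, float_format="%.6g")

    summary = summarize_variant(cells_df) if len(cells_df) else pd.DataFrame(
        columns=["variant_id", "parameter", "N", "mean", "se", "note"])
    paths["summary"] = out / "variants_summary.tsv"
    summary.to_csv(paths["summary"], sep="\t", index=False,
                   float_format="%.6g")

    # --- stats --------------------------------------------------------------
    comp_results, classes = [], []
    if len(cells_df) and cells_df["variant_id"].nunique() > 1:
        try:
            comp_results = compare_variants(
                cells_df, config.wild_type_id, method=config.stats_method,
                alpha=config.alpha, log=warnings_log.append)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"stats: {e}") from e
        by_variant: dict[str, list] = {}
        for r in comp_results:
            by_variant.setdefault(r.variant_id, []).append(r)
        for vid, results in by_variant.items():
            classes.append(classify_variant(results))
    comp_df = comparisons_to_frame(comp_results)
    paths["comparisons"] = out / "comparisons.tsv"
    comp_df.to_csv(paths["comparisons"], sep="\t", index=False,
                   float_format="%.6g")
    class_df = pd.DataFrame(
        [{"variant_id": c.variant_id, "label": c.label,
          "evidence": "; ".join(f"{r.parameter}:{r.direction}"
                                for r in c.evidence),
          "conflict": c.conflict} for c in classes],
        columns=["variant_id", "label", "evidence", "conflict"])
    paths["classification"] = out / "classification.tsv"
    class_df.to_csv(paths["classification"], sep="\t", index=False)

    # --- burden -------------------------------------------------------------
    try:
        burden_df = _burden_table(config)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"burden: {e}") from e
    paths["burden"] = out / "burden.tsv"
    burden_df.to_csv(paths["burden"], sep="\t", index=False)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"navclamp": _pkg_version, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "n_cells": int(len(cells_df)),
        "warnings": warnings_log,
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log(f"pipeline complete: {len(cells_df)} cells, "
        f"{len(comp_df)} comparisons -> {out}")
    return paths


def _burden_table(config: RunConfig) -> pd.DataFrame:
    records = variant_records()
    rows = []
    for selector, kwargs, label in [
            ("all", {}, "all_rare_carriers"),
            ("functional", {}, "functional_carriers"),
            ("functional", {"subcohort": "US"}, "functional_carriers_us"),
            ("sensitivity", {}, "functional_carriers_incl_intronic")]:
        n_cases = N_CASES_US if kwargs.get("subcohort") == "US" \
            else config.n_cases
        res = carrier_burden(records, n_cases, config.n_controls,
                             selector=selector, **kwargs)
        rows.append({"test": label, "case_carriers": res.table.a,
                     "n_cases": res.table.n_cases,
                     "control_carriers": res.table.b,
                     "n_controls": res.table.n_controls,
                     "case_percent": res.case_percent,
                     "p_one_tailed": res.p, "p_display": res.p_display})
    res = variant_level_burden(records)
    rows.append({"test": "variant_level", "case_carriers": res.table.a,
                 "n_cases": res.table.n_cases,
                 "control_carriers": res.table.b,
                 "n_controls": res.table.n_controls,
                 "case_percent": res.case_percent,
                 "p_one_tailed": res.p, "p_display": res.p_display})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int = 0, n_cells: int = 5,
                  out_dir: str | Path | None = None,
                  ) -> tuple[RunConfig, dict[str, PopulationSpec]]:
    """Miniature three-cohort dataset for fast end-to-end checks.

    Wild type, a wild-type-identical variant, and a variant with ten-fold
    reduced current density, ``n_cells`` cells each.  Cell-to-cell spread is
    kept tight (a few percent) so the density defect is detectable at this
    size; with so few cells per group the rank-based scheme cannot reach the
    corrected threshold, so the fixture pins the parametric scheme for all
    parameters.  Returns the run config (optionally already executed into
    ``out_dir``) and the cohort specs.
    """
    wt = biophysics_summary().iloc[0].to_dict()
    # tight SEs: cv = se*sqrt(n)/|mean| ~= 4-10% per parameter
    tight = {"se_Ipeak": 2.5, "se_act_V12": 0.35, "se_act_Vslope": 0.12,
             "se_inact_V12": 0.6, "se_inact_Vslope": 0.1,
             "se_tau_inact": 0.006, "se_tau_rec": 0.1}
    wt.update(tight)
    twin = dict(wt, variant_id="wt_twin")
    low = dict(wt, variant_id="low_density",
               Ipeak_density_pA_per_pF=wt["Ipeak_density_pA_per_pF"] / 10.0,
               se_Ipeak=tight["se_Ipeak"] / 10.0)
    cohorts = []
    for row in (wt, twin, low):
        row = dict(row)
        row["N_density"] = row["N_bio"] = row["N_rec"] = n_cells
        cohorts.append(row)
    cfg = RunConfig(cohorts=cohorts, seed=seed, noise_sd_pA=10.0,
                    stats_method="anova_games_howell")
    cfg.validate()
    specs = {row["variant_id"]: _cohort_spec(cfg, row) for row in cohorts}
    if out_dir is not None:
        run_pipeline(cfg, out_dir, log=lambda *_: None)
    return cfg, specs
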