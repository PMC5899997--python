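"""Study-level validation experiments: parameter recovery, star-pattern
reproduction, and family-wise error calibration.

These routines regenerate the whole functional study in silico — all 15
cohorts (wild type + 14 variants) at the published sample sizes — and measure
how the analysis and statistics behave over seeded replicates.  They back the
package's acceptance checks and are reusable for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import study_population_specs
from .gating_model import (PopulationSpec, build_standard_protocols,
                           child_rng, draw_biophysics, generate_cohort)
from .reference_data import PARAMETERS, WILD_TYPE_ID
from .trace_analysis import AnalysisConfig, analyze_cell, cells_to_frame
from .variant_stats import (DEFAULT_METHODS, bonferroni_threshold,
                            compare_variants, dunn_vs_control)

__all__ = [
    "simulate_study_cells",
    "replicate_star_sets",
    "null_family_wise_error",
    "study_specs",
]


def study_specs(seed: int = 0, scale: float = 1.0) -> list[PopulationSpec]:
    """Calibrated cohort specs for the full study (cached per process)."""
    return study_population_specs(seed=seed, scale=scale)


def simulate_study_cells(seed: int,
                         specs: Sequence[PopulationSpec] | None = None,
                         noise_sd_pA: float = 10.0) -> pd.DataFrame:
    """One full simulate+analyze replicate; returns the cells table.

    ``seed`` controls the replicate's randomness; the calibrated cohort means
    are seed-independent, so replicates differ only in cell-level draws and
    recording noise.
    """
    specs = specs if specs is not None else study_specs()
    protocols = build_standard_protocols()
    config = AnalysisConfig()
    rows = []
    for spec in specs:
        rep_spec = replace(spec, seed=seed, noise_sd_pA=noise_sd_pA)
        cells, _ = generate_cohort(rep_spec, protocols)
        rows.extend(analyze_cell(c, config) for c in cells)
    return cells_to_frame(rows)


def replicate_star_sets(n_reps: int, seed: int,
                        specs: Sequence[PopulationSpec] | None = None,
                        ) -> list[set[tuple[str, str]]]:
    """Significant (variant, parameter) sets over full-pipeline replicates."""
    specs = specs if specs is not None else study_specs()
    out = []
    for rep in range(n_reps):
        cells = simulate_study_cells(seed * 10_000 + rep, specs)
        results = compare_variants(cells, WILD_TYPE_ID)
        out.append({(r.variant_id, r.parameter) for r in results
                    if r.significant})
    return out


# ---------------------------------------------------------------------------
# fast null replicates


def _gh_critical_q(threshold: float, k: int,
                   df_grid: np.ndarray) -> np.ndarray:
    return np.array([stats.studentized_range.isf(threshold, k, df)
                     for df in df_grid])


def null_family_wise_error(n_reps: int, seed: int,
                           specs: Sequence[PopulationSpec] | None = None,
                           alpha: float = 0.05) -> float:
    """Fraction of null replicates with any Bonferroni-significant call.

    Every cohort keeps its published sample size but is drawn from the
    wild-type distribution (parameter-level draws; trace-level measurement
    noise is negligible beside the cell-to-cell spread, so this exercises the
    same statistics at a fraction of the cost).  Games-Howell significance is
    decided against critical values precomputed on a degrees-of-freedom grid;
    Dunn against the normal quantile.
    """
    specs = specs if specs is not None else study_specs()
    wt = next(s for s in specs if s.variant_id == WILD_TYPE_ID)
    k = len(specs)
    threshold = bonferroni_threshold(k - 1, len(PARAMETERS), alpha)
    df_grid = np.geomspace(3.0, 500.0, 40)
    log_df = np.log(df_grid)
    q_crit = _gh_critical_q(threshold, k, df_grid)
    z_crit = stats.norm.isf(threshold / 2.0)

    n_false = 0
    for rep in range(n_reps):
        frames = []
        for spec in specs:
            null_spec = replace(spec, param_means=wt.param_means,
                                param_cv=wt.param_cv,
                                observable_means=wt.observable_means)
            rng = child_rng(seed, spec.variant_id, f"null{rep}")
            frames.append(draw_biophysics(null_spec, rng=rng))
        df = pd.concat(frames, ignore_index=True)
        if _any_significant(df, k, q_crit, log_df, z_crit):
            n_false += 1
    return n_false / n_reps


def _any_significant(cells: pd.DataFrame, k: int, q_crit: np.ndarray,
                     log_df: np.ndarray, z_crit: float) -> bool:
    for param in PARAMETERS:
        series = cells[["variant_id", param]].dropna()
        wt_vals = series.loc[series["variant_id"] == WILD_TYPE_ID,
                             param].to_numpy(dtype=float)
        scheme = DEFAULT_METHODS[param]
        if scheme == "kw_dunn":
            groups, ids = [wt_vals], [WILD_TYPE_ID]
            for vid, grp in series.groupby("variant_id", sort=False):
                if vid != WILD_TYPE_ID:
                    groups.append(grp[param].to_numpy(dtype=float))
            for z, _p in dunn_vs_control(groups, 0):
                if math.isfinite(z) and abs(z) > z_crit:
                    return True
        else:
            nc = wt_vals.size
            mc, vc = wt_vals.mean(), wt_vals.var(ddof=1)
            for vid, grp in series.groupby("variant_id", sort=False):
                if vid == WILD_TYPE_ID:
                    continue
                vals = grp[param].to_numpy(dtype=float)
                n = vals.size
                if n < 2:
                    continue
                denom2 = vals.var(ddof=1) / n + vc / nc
                if denom2 == 0:
                    continue
                t = (vals.mean() - mc) / math.sqrt(denom2)
                df_w = denom2**2 / ((vals.var(ddof=1) / n)**2 / (n - 1)
                                    + (vc / nc)**2 / (nc - 1))
                qc = float(np.interp(math.log(df_w), log_df, q_crit))
                if abs(t) * math.sqrt(2.0) > qc:
                    return True
    return False
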