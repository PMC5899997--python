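"""Variant-vs-wild-type statistics and functional classification.

Each of the seven gating parameters is compared between every variant cohort
and the wild-type cohort with one of two post-hoc schemes the study names:

* Kruskal–Wallis rank-sum test with Dunn's pairwise comparisons against the
  control group (rank-based; used by default for the right-skewed positive
  parameters — current density and the two time constants);
* one-way ANOVA framework with the Games-Howell post-hoc test (Welch-type
  statistic referred to the studentized-range distribution; default for
  voltages and slope factors).

Significance is declared against a fixed Bonferroni threshold
``alpha / (n_variants * n_parameters)`` — 0.05/98 = 0.00051 for 14 variants
and seven parameters — and significant results are folded into a
gain-of-function / loss-of-function / wild-type-like call per variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference_data import PARAMETERS

__all__ = [
    "ComparisonResult",
    "FunctionalClass",
    "kruskal_wallis",
    "dunn_vs_control",
    "games_howell_vs_control",
    "bonferroni_threshold",
    "compare_variants",
    "classify_variant",
    "DEFAULT_METHODS",
]

Method = Literal["kw_dunn", "anova_games_howell"]

#: default post-hoc scheme per parameter: rank-based for skewed positive
#: quantities, Games-Howell for (approximately normal) voltages and slopes
DEFAULT_METHODS: dict[str, Method] = {
    "Ipeak_density_pA_per_pF": "kw_dunn",
    "act_V12_mV": "anova_games_howell",
    "act_Vslope_mV": "anova_games_howell",
    "inact_V12_mV": "anova_games_howell",
    "inact_Vslope_mV": "anova_games_howell",
    "tau_inact_0mV_ms": "kw_dunn",
    "tau_rec_ms": "kw_dunn",
}


@dataclass
class ComparisonResult:
    """One variant-vs-wild-type test for one parameter."""

    variant_id: str
    parameter: str
    method: Method
    statistic: float
    p_raw: float
    threshold: float
    significant: bool
    direction: Literal["higher", "lower", "none"]
    n_variant: int = 0
    n_control: int = 0
    mean_variant: float = math.nan
    mean_control: float = math.nan


@dataclass
class FunctionalClass:
    """Gain/loss-of-function call for one variant with its evidence."""

    variant_id: str
    label: Literal["gain_of_function", "loss_of_function", "wild_type_like"]
    evidence: list[ComparisonResult] = field(default_factory=list)
    conflict: bool = False


# ---------------------------------------------------------------------------
# tests


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    Degenerate input (every observation identical) returns ``(0, 1)``.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrs)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrs)
    return float(h), float(p)


def dunn_vs_control(groups: Sequence[np.ndarray], control_index: int,
                    ) -> list[tuple[float, float]]:
    """Dunn's rank comparison of every group against a control group.

    Ranks are pooled once across all groups; for group *i* the statistic is

        z_i = (meanrank_i - meanrank_ctrl)
              / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_ctrl)),

    with tie correction ``T = sum(t^3 - t) / (12 (N-1))``, referred to the
    standard normal (two-sided).  Returns ``(z, p)`` per non-control group, in
    group order; groups with fewer than 2 observations yield ``(nan, nan)``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, idx = [], 0
    for a in arrs:
        mean_ranks.append(ranks[idx:idx + a.size].mean() if a.size else math.nan)
        idx += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_ctrl = arrs[control_index].size
    out = []
    for i, a in enumerate(arrs):
        if i == control_index:
            continue
        if a.size < 2 or n_ctrl < 2 or var_base <= 0:
            out.append((math.nan, math.nan))
            continue
        se = math.sqrt(var_base * (1.0 / a.size + 1.0 / n_ctrl))
        z = (mean_ranks[i] - mean_ranks[control_index]) / se
        out.append((float(z), float(2.0 * stats.norm.sf(abs(z)))))
    return out


def games_howell_vs_control(groups: Sequence[np.ndarray], control_index: int,
                            ) -> list[tuple[float, float, float]]:
    """Games-Howell comparison of every group against a control group.

    For group *i* the Welch-type statistic
    ``t = (mean_i - mean_c) / sqrt(s_i^2/n_i + s_c^2/n_c)`` with
    Welch–Satterthwaite degrees of freedom is referred to the studentized-range
    distribution with ``k = len(groups)`` at ``q = |t| * sqrt(2)``.  Returns
    ``(q, df, p)`` per non-control group; groups smaller than 2 yield NaNs.
    With only two groups the procedure reduces to Welch's t-test.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    c = arrs[control_index]
    nc = c.size
    vc = float(np.var(c, ddof=1)) if nc > 1 else math.nan
    out = []
    for i, a in enumerate(arrs):
        if i == control_index:
            continue
        n = a.size
        if n < 2 or nc < 2:
            out.append((math.nan, math.nan, math.nan))
            continue
        v = float(np.var(a, ddof=1))
        denom2 = v / n + vc / nc
        if denom2 == 0:
            diff = float(np.mean(a) - np.mean(c))
            out.append((0.0 if diff == 0 else math.inf, float(n + nc - 2),
                        1.0 if diff == 0 else 0.0))
            continue
        t = (float(np.mean(a)) - float(np.mean(c))) / math.sqrt(denom2)
        df = denom2**2 / ((v / n)**2 / (n - 1) + (vc / nc)**2 / (nc - 1))
        q = abs(t) * math.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df))
        out.append((float(q), float(df), min(max(p, 0.0), 1.0)))
    return out


def bonferroni_threshold(n_variants: int, n_parameters: int,
                         alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / (n_variants * n_parameters)."""
    if n_variants < 1 or n_parameters < 1:
        raise ValueError("counts must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_variants * n_parameters)


# ---------------------------------------------------------------------------
# study-level comparison and classification


def compare_variants(cells: pd.DataFrame, wild_type_id: str,
                     method: Method | Mapping[str, Method] | None = None,
                     alpha: float = 0.05,
                     log=None) -> list[ComparisonResult]:
    """Run every variant x parameter comparison against the wild-type cohort.

    ``cells`` is a cells.tsv-shaped frame (one row per cell with the seven
    parameters and QC flags).  Density comparisons use the density QC tier,
    everything else the biophysics tier; the recovery constant additionally
    requires the cell to have a recovery measurement.  ``method`` may be a
    single scheme for all parameters or a per-parameter mapping (defaults to
    :data:`DEFAULT_METHODS`).  The significance threshold is
    ``bonferroni_threshold(n_variants, 7, alpha)``.
    """
    log = log or (lambda msg: None)
    if isinstance(method, str):
        methods: Mapping[str, Method] = {p: method for p in PARAMETERS}
    else:
        methods = dict(DEFAULT_METHODS) | dict(method or {})
    variant_ids = [v for v in cells["variant_id"].unique() if v != wild_type_id]
    if wild_type_id not in set(cells["variant_id"]):
        raise ValueError(f"wild-type cohort {wild_type_id!r} missing")
    threshold = bonferroni_threshold(max(len(variant_ids), 1), len(PARAMETERS),
                                     alpha)
    results: list[ComparisonResult] = []
    for param in PARAMETERS:
        tier = cells[cells["qc_density_pass"]] \
            if param == "Ipeak_density_pA_per_pF" \
            else cells[cells["qc_biophysics_pass"]]
        groups, ids = [], []
        for vid in [wild_type_id, *variant_ids]:
            vals = tier.loc[tier["variant_id"] == vid, param].dropna()
            if len(vals) < 2:
                if vid != wild_type_id:
                    log(f"{vid}/{param}: fewer than 2 cells, comparison skipped")
                continue
            groups.append(vals.to_numpy(dtype=float))
            ids.append(vid)
        if not groups or ids[0] != wild_type_id:
            log(f"{param}: wild-type group unavailable, parameter skipped")
            continue
        scheme = methods[param]
        if scheme == "kw_dunn":
            stats_list = [(z, p) for z, p in dunn_vs_control(groups, 0)]
        elif scheme == "anova_games_howell":
            stats_list = [(q, p) for q, _, p in
                          games_howell_vs_control(groups, 0)]
        else:
            raise ValueError(f"unknown method {scheme!r}")
        wt_mean = float(np.mean(groups[0]))
        for (stat, p), vid, grp in zip(stats_list, ids[1:], groups[1:]):
            if not math.isfinite(p):
                log(f"{vid}/{param}: test undefined, result absent")
                continue
            sig = bool(p < threshold)
            diff = float(np.mean(grp)) - wt_mean
            direction = "none" if not sig else ("higher" if diff > 0 else "lower")
            results.append(ComparisonResult(
                variant_id=vid, parameter=param, method=scheme,
                statistic=float(stat), p_raw=float(p), threshold=threshold,
                significant=sig, direction=direction,
                n_variant=len(grp), n_control=len(groups[0]),
                mean_variant=float(np.mean(grp)), mean_control=wt_mean))
    return results


def _density_reduced(r: ComparisonResult) -> bool:
    # density is negative (inward); reduced magnitude means a signed increase
    return abs(r.mean_variant) < abs(r.mean_control)


#: (parameter, predicate on the significant result) -> gain-of-function
_GOF_RULES = {
    "inact_V12_mV": lambda r: r.direction == "higher",      # depolarised shift
    "tau_rec_ms": lambda r: r.direction == "lower",         # faster recovery
    "tau_inact_0mV_ms": lambda r: r.direction == "higher",  # slower inactivation
    "inact_Vslope_mV": lambda r: r.direction == "higher",   # shallower curve
}
#: -> loss-of-function
_LOF_RULES = {
    "Ipeak_density_pA_per_pF": _density_reduced,
    "inact_V12_mV": lambda r: r.direction == "lower",       # hyperpolarised
    "tau_rec_ms": lambda r: r.direction == "higher",        # slower recovery
}


def classify_variant(results: Sequence[ComparisonResult]) -> FunctionalClass:
    """Gain/loss-of-function call from one variant's comparison results.

    Precedence: no significant parameter -> wild-type-like; any significant
    inactivation-impairing change -> gain of function (wins over coexisting
    loss-of-function evidence, which is recorded as a conflict); otherwise
    significant density reduction, hyperpolarised availability or slower
    recovery -> loss of function.  Significant changes that fit neither
    pattern (e.g. an activation-slope change alone) do not alter the call.
    """
    if not results:
        raise ValueError("no comparison results supplied")
    variant_ids = {r.variant_id for r in results}
    if len(variant_ids) != 1:
        raise ValueError("results must belong to a single variant")
    vid = variant_ids.pop()
    sig = [r for r in results if r.significant]
    gof = [r for r in sig if _GOF_RULES.get(r.parameter, lambda _: False)(r)]
    lof = [r for r in sig if _LOF_RULES.get(r.parameter, lambda _: False)(r)]
    if gof:
        return FunctionalClass(variant_id=vid, label="gain_of_function",
                               evidence=gof + lof, conflict=bool(lof))
    if lof:
        return FunctionalClass(variant_id=vid, label="loss_of_function",
                               evidence=lof)
    return FunctionalClass(variant_id=vid, label="wild_type_like", evidence=[])


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    cols = ["variant_id", "parameter", "method", "statistic", "p_raw",
            "threshold", "significant", "direction", "n_variant", "n_control",
            "mean_variant", "mean_control"]
    return pd.DataFrame([{k: getattr(r, k) for k in cols} for r in results],
                        columns=cols)
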