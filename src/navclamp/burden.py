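"""Rare-variant filtering and case-control burden tests.

The study's headline statistics are one-tailed Fisher exact tests on carrier
counts: qualifying SCN4A variants (novel, or ExAC allele frequency below
5e-5) are tallied per cohort, and enrichment in cases is tested with the
hypergeometric upper tail.  Carrier-level tests count individuals (no carrier
in the study had two qualifying variants); the variant-level test counts
distinct variants that were functionally disruptive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "BurdenTable",
    "BurdenResult",
    "maf_filter",
    "fisher_one_tailed",
    "carrier_burden",
    "variant_level_burden",
    "MAF_THRESHOLD",
]

#: ExAC allele-frequency cut defining "ultra-rare" in the study
MAF_THRESHOLD = 5e-5

DISRUPTIVE_LABELS = {"gain_of_function", "loss_of_function"}

Selector = Literal["all", "functional", "sensitivity"]


@dataclass(frozen=True)
class BurdenTable:
    """2x2 carrier table: a of n_cases vs b of n_controls."""

    a: int
    n_cases: int
    b: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n_cases and 0 <= self.b <= self.n_controls):
            raise ValueError("carrier counts must lie within cohort sizes")


@dataclass
class BurdenResult:
    """Outcome of one burden test."""

    table: BurdenTable
    p: float
    case_percent: float
    selector: str
    note: str = ""

    @property
    def p_display(self) -> float:
        """p rounded to two significant figures, as reported."""
        if self.p <= 0:
            return 0.0
        ndigits = 1 - int(math.floor(math.log10(self.p)))
        return round(self.p, ndigits)


def maf_filter(records: pd.DataFrame, threshold: float = MAF_THRESHOLD,
               protein_altering_only: bool = True) -> pd.DataFrame:
    """Keep variants that are novel or rarer than ``threshold`` (strict <).

    ``exac_af`` is NaN/None for novel variants.  With
    ``protein_altering_only`` (the study's primary filter) intronic records
    are dropped as well.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    af = pd.to_numeric(records["exac_af"], errors="coerce")
    keep = af.isna() | (af < threshold)
    if protein_altering_only:
        keep &= records["consequence"] != "intronic"
    return records[keep].copy()


def fisher_one_tailed(table: BurdenTable) -> float:
    """Exact one-tailed Fisher p for enrichment in cases, P(X >= a).

    The hypergeometric tail with fixed margins: ``X`` counts carrier slots
    falling in the case cohort among ``a + b`` total carriers drawn from
    ``n_cases + n_controls`` individuals.
    """
    m = table.n_cases + table.n_controls
    k = table.a + table.b
    return float(stats.hypergeom.sf(table.a - 1, m, k, table.n_cases))


def _select(records: pd.DataFrame, selector: Selector) -> pd.DataFrame:
    rare = maf_filter(records, protein_altering_only=False)
    if selector == "all":
        return rare
    if selector == "functional":
        return rare[rare["functional_class"].isin(DISRUPTIVE_LABELS)]
    if selector == "sensitivity":
        # intronic control variant counted as deleterious
        return rare[rare["functional_class"].isin(DISRUPTIVE_LABELS)
                    | (rare["consequence"] == "intronic")]
    raise ValueError(f"unknown selector {selector!r}")


def carrier_burden(records: pd.DataFrame, n_cases: int, n_controls: int,
                   selector: Selector = "functional",
                   case_cohorts: Sequence[str] = ("case",),
                   subcohort: str | None = None) -> BurdenResult:
    """Carrier-level Fisher test for the records chosen by ``selector``.

    * ``all`` — every rare variant (including the intronic one);
    * ``functional`` — rare protein-altering variants with a functionally
      disruptive label;
    * ``sensitivity`` — as ``functional`` but counting the control intronic
      variant as deleterious.

    ``subcohort`` restricts case carriers to one recruitment arm (e.g. "US")
    while keeping the full case denominator supplied in ``n_cases``.  Each
    record contributes ``carrier_count`` individuals (one in the study).
    """
    chosen = _select(records, selector)
    if subcohort is not None:
        in_case = chosen["cohort"].isin(case_cohorts)
        chosen = chosen[~in_case | (chosen["subcohort"] == subcohort)]
    is_case = chosen["cohort"].isin(case_cohorts)
    a = int(chosen.loc[is_case, "carrier_count"].sum())
    b = int(chosen.loc[~is_case, "carrier_count"].sum())
    table = BurdenTable(a=a, n_cases=n_cases, b=b, n_controls=n_controls)
    note = ""
    if len(chosen) == 0:
        note = "selector matched no records"
        return BurdenResult(table=table, p=1.0, case_percent=0.0,
                            selector=selector, note=note)
    p = fisher_one_tailed(table)
    pct = round(100.0 * a / n_cases, 1)
    return BurdenResult(table=table, p=p, case_percent=pct,
                        selector=selector, note=note)


def variant_level_burden(records: pd.DataFrame) -> BurdenResult:
    """Variant-level Fisher test: disruptive vs non-disruptive variants.

    Rows are distinct rare variants rather than carriers; the case column
    counts functionally disruptive case variants, the denominator per cohort
    is the number of rare variants found there (the control denominator
    includes the intronic variant, which was not functionally disruptive).
    """
    rare = maf_filter(records, protein_altering_only=False)
    is_case = rare["cohort"] == "case"
    disruptive = rare["functional_class"].isin(DISRUPTIVE_LABELS)
    a = int((is_case & disruptive).sum())
    b = int((~is_case & disruptive).sum())
    n_case_var = int(is_case.sum())
    n_ctrl_var = int((~is_case).sum())
    table = BurdenTable(a=a, n_cases=n_case_var, b=b, n_controls=n_ctrl_var)
    if a + b == 0:
        return BurdenResult(table=table, p=1.0, case_percent=0.0,
                            selector="variant_level",
                            note="no disruptive variants")
    p = fisher_one_tailed(table)
    pct = round(100.0 * a / n_case_var, 1) if n_case_var else 0.0
    return BurdenResult(table=table, p=p, case_percent=pct,
                        selector="variant_level")
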