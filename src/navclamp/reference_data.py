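"""Bundled summary data from the NaV1.4 / SCN4A SIDS case-control functional study.

Two tables are shipped as plain Python literals:

* :func:`biophysics_summary` — per-variant mean (SE) and N for the seven analysed
  gating parameters of wild-type NaV1.4 and the 14 rare variants expressed in
  HEK293 cells, plus the published significance pattern (which variant/parameter
  cells crossed the Bonferroni threshold) and functional labels.
* :func:`variant_records` — the rare-variant carrier table for the case-control
  comparison (278 SIDS cases, 729 controls): ExAC allele frequency, consequence,
  cohort, and functional classification of each qualifying SCN4A variant.

These printed summaries are the inputs from which synthetic cohorts are built;
no raw recordings exist for the study.
"""

from __future__ import annotations

import pandas as pd

N_CASES = 278
N_CASES_UK = 84
N_CASES_US = 194
N_CONTROLS = 729

#: the seven analysed per-cell biophysical parameters (column names of cells.tsv)
PARAMETERS = (
    "Ipeak_density_pA_per_pF",
    "act_V12_mV",
    "act_Vslope_mV",
    "inact_V12_mV",
    "inact_Vslope_mV",
    "tau_inact_0mV_ms",
    "tau_rec_ms",
)

WILD_TYPE_ID = "wild_type"

# Per-variant rows: N_density, Ipeak mean/SE, N_bio, activation V1/2 & slope,
# fast-inactivation V1/2 & slope, tau_inact at 0 mV, N_rec, tau_recovery at -80 mV.
# Wild-type SEs printed as 0.0 are below printed precision; 0.04 mV / 0.004 ms are
# used (half the rounding unit) where a nonzero SD is needed.
_SUMMARY_ROWS = [
    # variant_id, cohort, N_dens, Ipeak, seI, N_bio, aV12, se, aVs, se,
    #   iV12, se, iVs, se, tauI, se, N_rec, tauR, se
    ("wild_type", "wt", 149, -127.5, 6.4, 146, -19.5, 0.2, 6.4, 0.1,
     -65.3, 0.3, 5.4, 0.04, 0.30, 0.004, 105, 5.63, 0.14),
    ("Ser682Trp", "case", 19, -94.2, 9.9, 17, -21.2, 0.7, 7.2, 0.2,
     -67.0, 0.6, 5.9, 0.2, 0.40, 0.02, 17, 6.15, 0.33),
    ("Gly859Arg", "case", 18, -138.5, 16.4, 17, -20.2, 0.8, 5.7, 0.2,
     -64.2, 0.6, 5.1, 0.1, 0.31, 0.01, 17, 5.20, 0.30),
    ("Val1442Met", "case", 14, -145.5, 21.7, 14, -21.7, 0.8, 6.3, 0.2,
     -71.9, 1.0, 5.2, 0.1, 0.27, 0.01, 13, 8.51, 0.46),
    ("Arg1463Ser", "case", 27, -71.3, 8.3, 25, -17.4, 0.5, 6.7, 0.2,
     -61.7, 0.6, 6.3, 0.1, 0.31, 0.01, 19, 1.95, 0.09),
    ("Met1493Val", "case", 17, -78.2, 8.3, 17, -19.2, 0.5, 6.7, 0.3,
     -65.3, 0.8, 5.5, 0.2, 0.29, 0.01, 7, 5.76, 0.47),
    ("Glu1520Lys", "case", 39, -49.8, 9.7, 28, -20.3, 0.4, 6.3, 0.1,
     -66.3, 0.5, 5.4, 0.2, 0.33, 0.01, 20, 5.63, 0.29),
    ("Arg179Gln", "control", 11, -117.6, 11.0, 11, -19.3, 0.6, 6.5, 0.2,
     -65.1, 0.7, 5.1, 0.1, 0.25, 0.01, 11, 4.73, 0.30),
    ("Arg190Trp", "control", 14, -153.4, 21.8, 14, -20.7, 0.5, 6.4, 0.2,
     -64.9, 0.5, 5.3, 0.1, 0.29, 0.01, 13, 5.09, 0.20),
    ("Leu227Phe", "control", 12, -107.7, 16.1, 12, -17.6, 0.4, 6.5, 0.2,
     -67.8, 0.8, 5.6, 0.1, 0.33, 0.02, 10, 5.33, 0.30),
    ("Asp334Asn", "control", 10, -141.0, 26.6, 10, -21.0, 0.9, 6.4, 0.2,
     -66.4, 0.8, 5.3, 0.1, 0.27, 0.01, 9, 5.07, 0.30),
    ("Gly863Arg", "control", 12, -124.6, 15.8, 12, -20.3, 0.8, 6.3, 0.1,
     -66.1, 0.7, 5.2, 0.2, 0.29, 0.01, 10, 5.71, 0.21),
    ("Ala870Thr", "control", 16, -132.6, 20.0, 15, -20.0, 0.6, 6.4, 0.1,
     -65.7, 0.6, 5.0, 0.1, 0.29, 0.01, 14, 6.29, 0.55),
    ("Met897Lys", "control", 10, -102.8, 23.3, 9, -20.4, 0.7, 6.8, 0.3,
     -67.7, 1.3, 5.5, 0.2, 0.31, 0.02, 7, 6.21, 0.54),
    ("Val1590Ile", "control", 8, -92.8, 13.2, 8, -20.7, 0.6, 6.8, 0.2,
     -65.8, 0.9, 5.4, 0.2, 0.30, 0.02, 7, 5.73, 0.61),
]

_SUMMARY_COLUMNS = [
    "variant_id", "cohort", "N_density", "Ipeak_density_pA_per_pF", "se_Ipeak",
    "N_bio", "act_V12_mV", "se_act_V12", "act_Vslope_mV", "se_act_Vslope",
    "inact_V12_mV", "se_inact_V12", "inact_Vslope_mV", "se_inact_Vslope",
    "tau_inact_0mV_ms", "se_tau_inact", "N_rec", "tau_rec_ms", "se_tau_rec",
]

#: (variant_id, parameter) cells that crossed the Bonferroni threshold in the study
PUBLISHED_STARS = frozenset({
    ("Ser682Trp", "act_Vslope_mV"),
    ("Ser682Trp", "tau_inact_0mV_ms"),
    ("Val1442Met", "inact_V12_mV"),
    ("Val1442Met", "tau_rec_ms"),
    ("Arg1463Ser", "Ipeak_density_pA_per_pF"),
    ("Arg1463Ser", "inact_V12_mV"),
    ("Arg1463Ser", "inact_Vslope_mV"),
    ("Arg1463Ser", "tau_rec_ms"),
    ("Glu1520Lys", "Ipeak_density_pA_per_pF"),
})

#: published functional-expression labels of the 14 coding variants
PUBLISHED_LABELS = {
    "Ser682Trp": "gain_of_function",
    "Gly859Arg": "wild_type_like",
    "Val1442Met": "loss_of_function",
    "Arg1463Ser": "gain_of_function",
    "Met1493Val": "wild_type_like",
    "Glu1520Lys": "loss_of_function",
    "Arg179Gln": "wild_type_like",
    "Arg190Trp": "wild_type_like",
    "Leu227Phe": "wild_type_like",
    "Asp334Asn": "wild_type_like",
    "Gly863Arg": "wild_type_like",
    "Ala870Thr": "wild_type_like",
    "Met897Lys": "wild_type_like",
    "Val1590Ile": "wild_type_like",
}

# variant_id, cdna_change, cohort, subcohort, exac_af (None = novel), consequence,
# functional label (None for the intronic variant, which was not expressed)
_VARIANT_ROWS = [
    ("Ser682Trp", "2045C>G", "case", "US", 2.626e-5, "missense", "gain_of_function"),
    ("Gly859Arg", "2575G>A", "case", "US", 1.756e-5, "missense", "wild_type_like"),
    ("Val1442Met", "4324G>A", "case", "US", 1.025e-5, "missense", "loss_of_function"),
    ("Arg1463Ser", "4387C>A", "case", "UK", 0.832e-5, "missense", "gain_of_function"),
    ("Met1493Val", "4477A>G", "case", "US", None, "missense", "wild_type_like"),
    ("Glu1520Lys", "4558G>A", "case", "US", None, "missense", "loss_of_function"),
    ("intron_393-1C>T", "393-1C>T", "control", None, None, "intronic", None),
    ("Arg179Gln", "536G>A", "control", None, 1.862e-5, "missense", "wild_type_like"),
    ("Arg190Trp", "568C>T", "control", None, None, "missense", "wild_type_like"),
    ("Leu227Phe", "679C>T", "control", None, 4.441e-5, "missense", "wild_type_like"),
    ("Asp334Asn", "1000G>A", "control", None, 2.484e-5, "missense", "wild_type_like"),
    ("Gly863Arg", "2587G>A", "control", None, 1.581e-5, "missense", "wild_type_like"),
    ("Ala870Thr", "2608G>A", "control", None, None, "missense", "wild_type_like"),
    ("Met897Lys", "2690T>A", "control", None, None, "missense", "wild_type_like"),
    ("Val1590Ile", "4768G>A", "control", None, 0.8278e-5, "missense", "wild_type_like"),
]


def biophysics_summary() -> pd.DataFrame:
    """Published per-variant gating-parameter summary (mean, SE, N) as a DataFrame."""
    return pd.DataFrame(_SUMMARY_ROWS, columns=_SUMMARY_COLUMNS)


def variant_records() -> pd.DataFrame:
    """Rare-variant carrier table for the case-control burden tests.

    One row per distinct qualifying SCN4A variant; every variant had exactly one
    carrier in the study, so ``carrier_count`` is 1 throughout.
    """
    df = pd.DataFrame(
        _VARIANT_ROWS,
        columns=["variant_id", "cdna_change", "cohort", "subcohort", "exac_af",
                 "consequence", "functional_class"],
    )
    df["carrier_count"] = 1
    return df
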