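import math

import pytest

from navclamp.gating_model import (GatingParams, PopulationSpec,
                                   build_standard_protocols)
from navclamp.reference_data import biophysics_summary

#: observable-parameter name -> latent GatingParams field
OBS_TO_LATENT = {
    "Ipeak_density_pA_per_pF": "gmax_density",
    "act_V12_mV": "act_V12_mV",
    "act_Vslope_mV": "act_slope_mV",
    "inact_V12_mV": "inact_V12_mV",
    "inact_Vslope_mV": "inact_slope_mV",
    "tau_inact_0mV_ms": "tau_inact_0mV_ms",
    "tau_rec_ms": "tau_rec_m80mV_ms",
}


@pytest.fixture(scope="session")
def protocols():
    return build_standard_protocols()


@pytest.fixture(scope="session")
def wt_params():
    """Wild-type latent parameters (uncalibrated defaults)."""
    return GatingParams()


@pytest.fixture(scope="session")
def summary():
    return biophysics_summary()


def spec_from_row(row, seed=0, n_cells=None, n_recovery=None):
    """Parameter-level cohort spec straight from a summary row (no trace
    calibration): observable means from the row, per-field CV from SE*sqrt(N).

    Sufficient for statistics tests that draw measured-parameter tables
    directly.
    """
    targets = {
        "Ipeak_density_pA_per_pF": float(row["Ipeak_density_pA_per_pF"]),
        "act_V12_mV": float(row["act_V12_mV"]),
        "act_Vslope_mV": float(row["act_Vslope_mV"]),
        "inact_V12_mV": float(row["inact_V12_mV"]),
        "inact_Vslope_mV": float(row["inact_Vslope_mV"]),
        "tau_inact_0mV_ms": float(row["tau_inact_0mV_ms"]),
        "tau_rec_ms": float(row["tau_rec_ms"]),
    }
    ses = {
        "Ipeak_density_pA_per_pF": (row["se_Ipeak"], row["N_density"]),
        "act_V12_mV": (row["se_act_V12"], row["N_bio"]),
        "act_Vslope_mV": (row["se_act_Vslope"], row["N_bio"]),
        "inact_V12_mV": (row["se_inact_V12"], row["N_bio"]),
        "inact_Vslope_mV": (row["se_inact_Vslope"], row["N_bio"]),
        "tau_inact_0mV_ms": (row["se_tau_inact"], row["N_bio"]),
        "tau_rec_ms": (row["se_tau_rec"], row["N_rec"]),
    }
    cv = {OBS_TO_LATENT[k]: float(se) * math.sqrt(n) / abs(targets[k])
          for k, (se, n) in ses.items()}
    return PopulationSpec(
        variant_id=str(row["variant_id"]),
        n_cells=int(row["N_density"]) if n_cells is None else n_cells,
        param_means=GatingParams(), param_cv=cv, seed=seed,
        n_recovery=int(row["N_rec"]) if n_recovery is None else n_recovery,
        observable_means=targets)
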