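"""Hodgkin–Huxley style simulator for whole-cell NaV1.4 voltage-clamp recordings.

The channel is modelled with the minimal gating scheme that reproduces the
measured quantities: conductance ``g = gmax * m(t)**p * h(t)`` with activation
gates ``m`` and a single fast-inactivation gate ``h`` relaxing exponentially
toward their voltage-dependent steady states,

    dm/dt = (m_inf(V) - m) / tau_m(V),     dh/dt = (h_inf(V) - h) / tau_h(V).

Within each constant-voltage epoch of a protocol these equations have exact
exponential solutions, so sweeps are integrated in closed form (no ODE-solver
error); the sample-interval accuracy contract below concerns only how finely
the resulting trace is sampled.

Steady states are Boltzmann functions.  The *open-probability* voltage
dependence is the experimentally fitted object, so the single-gate steady state
is the p-th root of the activation Boltzmann: ``m_inf = B_act(V)**(1/p)``.  In
the instantaneous-gating limit the peak-conductance curve then equals
``B_act(V)`` exactly and the availability curve equals the decreasing
inactivation Boltzmann exactly.

The inactivation time constant ``tau_h(V)`` is pinned at two voltages the study
measures — the open-state decay at 0 mV and recovery at -80 mV — and is
log-linearly interpolated in between, clamped outside.  The activation time
constant has a mild bell-shaped voltage dependence around the activation
midpoint and is parameterised by its value at 0 mV.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SWEEP",
    "Epoch",
    "VoltageProtocol",
    "GatingParams",
    "PopulationSpec",
    "SweepRecording",
    "CellRecording",
    "InvalidParameterError",
    "SimulationAccuracyError",
    "steady_state_gate",
    "gate_time_constant",
    "simulate_sweep",
    "simulate_cell",
    "build_standard_protocols",
    "generate_cohort",
    "draw_biophysics",
    "child_rng",
]

#: sentinel marking the sweep-variable voltage or duration of an epoch
SWEEP = "SWEEP"


class InvalidParameterError(ValueError):
    """A gating or population parameter violates its physical constraints."""


class SimulationAccuracyError(ValueError):
    """The sample interval is too coarse to resolve the fastest gate."""


def child_rng(seed: int, *names: str) -> np.random.Generator:
    """Named random stream derived from a global seed.

    Streams are keyed by name (CRC32), so adding or reordering cohorts does not
    perturb the draws of the others.
    """
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))


# ---------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class Epoch:
    """One constant-voltage segment of a clamp protocol.

    Either ``voltage_mV`` or ``duration_ms`` (never both) may be the
    :data:`SWEEP` sentinel, in which case the per-sweep value is substituted
    from the protocol's ``sweep_values``.
    """

    label: str
    voltage_mV: float | str
    duration_ms: float | str


@dataclass(frozen=True)
class VoltageProtocol:
    """Epoch-based description of one voltage-clamp experiment."""

    name: str
    holding_mV: float
    epochs: tuple[Epoch, ...]
    sweep_values: tuple[float, ...]
    sample_interval_ms: float = 0.02

    def __post_init__(self) -> None:
        if self.sample_interval_ms <= 0:
            raise InvalidParameterError("sample_interval_ms must be > 0")
        if len(self.sweep_values) < 1:
            raise InvalidParameterError("at least one sweep value is required")
        n_var = 0
        for ep in self.epochs:
            if ep.voltage_mV == SWEEP and ep.duration_ms == SWEEP:
                raise InvalidParameterError(
                    f"epoch {ep.label!r}: voltage and duration cannot both vary")
            if ep.voltage_mV == SWEEP or ep.duration_ms == SWEEP:
                n_var += 1
            if ep.duration_ms != SWEEP and ep.duration_ms <= 0:
                raise InvalidParameterError(
                    f"epoch {ep.label!r}: duration must be > 0")
        if n_var != 1:
            raise InvalidParameterError("exactly one epoch must be sweep-variable")
        if self.sweep_dimension == "duration" and any(
                v < 0 for v in self.sweep_values):
            raise InvalidParameterError("sweep durations must be >= 0")

    @property
    def sweep_dimension(self) -> Literal["voltage", "duration"]:
        for ep in self.epochs:
            if ep.voltage_mV == SWEEP:
                return "voltage"
            if ep.duration_ms == SWEEP:
                return "duration"
        raise InvalidParameterError("no sweep-variable epoch")  # pragma: no cover

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_values)

    def resolved_epochs(self, sweep_index: int) -> list[tuple[str, float, float]]:
        """Epochs of one sweep as ``(label, voltage_mV, duration_ms)`` triples.

        Duration-variable sweeps are padded with extra time at the final epoch
        so that every sweep of the protocol has the same total duration (the
        sweep matrices stay rectangular).
        """
        value = float(self.sweep_values[sweep_index])
        out = []
        for ep in self.epochs:
            v = value if ep.voltage_mV == SWEEP else float(ep.voltage_mV)
            d = value if ep.duration_ms == SWEEP else float(ep.duration_ms)
            out.append((ep.label, v, d))
        if self.sweep_dimension == "duration":
            pad = max(self.sweep_values) - value
            if pad > 0:
                label, v, d = out[-1]
                out[-1] = (label, v, d + pad)
        return out

    def epoch_samples(self, sweep_index: int) -> list[tuple[str, float, int]]:
        """Per-epoch ``(label, voltage, n_samples)`` on the sampling grid."""
        dt = self.sample_interval_ms
        return [(label, v, int(round(d / dt)))
                for label, v, d in self.resolved_epochs(sweep_index)]

    def n_samples(self, sweep_index: int = 0) -> int:
        return sum(n for _, _, n in self.epoch_samples(sweep_index))

    def time_axis(self, sweep_index: int = 0) -> np.ndarray:
        return np.arange(self.n_samples(sweep_index)) * self.sample_interval_ms

    def epoch_bounds(self, sweep_index: int = 0) -> dict[str, tuple[float, float]]:
        """Start/end time (ms) of each epoch, keyed by label."""
        bounds, t = {}, 0.0
        for label, _, n in self.epoch_samples(sweep_index):
            d = n * self.sample_interval_ms
            bounds[label] = (t, t + d)
            t += d
        return bounds

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "holding_mV": self.holding_mV,
            "epochs": [[ep.label, ep.voltage_mV, ep.duration_ms] for ep in self.epochs],
            "sweep_values": list(self.sweep_values),
            "sample_interval_ms": self.sample_interval_ms,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VoltageProtocol":
        return cls(
            name=d["name"],
            holding_mV=float(d["holding_mV"]),
            epochs=tuple(Epoch(*e) for e in d["epochs"]),
            sweep_values=tuple(float(v) for v in d["sweep_values"]),
            sample_interval_ms=float(d["sample_interval_ms"]),
        )


def build_standard_protocols(sample_interval_ms: float = 0.02,
                             ) -> dict[str, VoltageProtocol]:
    """The three standard protocols of the study, on a common sampling grid.

    * ``activation`` — 20 ms test steps from -100 to +50 mV in 10 mV
      increments (16 sweeps) from a holding voltage of -80 mV.
    * ``inactivation`` — 150 ms prepulses from -150 to 0 mV (16 sweeps)
      followed by a tail step to -10 mV.
    * ``recovery`` — paired 10 ms pulses to 0 mV separated by a variable
      interval at -80 mV (0, 1, 2, 5, 10, 20 ms plus 30 and 50 ms points).
    """
    dt = sample_interval_ms
    activation = VoltageProtocol(
        name="activation", holding_mV=-80.0,
        epochs=(Epoch("pre", -80.0, 5.0),
                Epoch("test", SWEEP, 20.0),
                Epoch("post", -80.0, 2.0)),
        sweep_values=tuple(float(v) for v in range(-100, 60, 10)),
        sample_interval_ms=dt)
    inactivation = VoltageProtocol(
        name="inactivation", holding_mV=-80.0,
        epochs=(Epoch("pre", -80.0, 5.0),
                Epoch("prepulse", SWEEP, 150.0),
                Epoch("tail", -10.0, 10.0),
                Epoch("post", -80.0, 2.0)),
        sweep_values=tuple(float(v) for v in range(-150, 10, 10)),
        sample_interval_ms=dt)
    recovery = VoltageProtocol(
        name="recovery", holding_mV=-80.0,
        epochs=(Epoch("pre", -80.0, 5.0),
                Epoch("p1", 0.0, 10.0),
                Epoch("interval", -80.0, SWEEP),
                Epoch("p2", 0.0, 10.0),
                Epoch("post", -80.0, 2.0)),
        sweep_values=(0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 50.0),
        sample_interval_ms=dt)
    return {"activation": activation, "inactivation": inactivation,
            "recovery": recovery}


# ---------------------------------------------------------------------------
# gating parameters


@dataclass(frozen=True)
class GatingParams:
    """Ground-truth channel parameters of one simulated cell.

    Voltages in mV, time constants in ms, ``gmax_density`` in nS/pF.
    ``tau_act_ms`` is the activation time constant at 0 mV; ``gate_exponent``
    is the number of independent activation gates.
    """

    gmax_density: float = 10.0
    E_rev_mV: float = 65.0
    act_V12_mV: float = -19.5
    act_slope_mV: float = 6.4
    inact_V12_mV: float = -65.3
    inact_slope_mV: float = 5.4
    tau_inact_0mV_ms: float = 0.30
    tau_rec_m80mV_ms: float = 5.63
    tau_act_ms: float = 0.2
    gate_exponent: int = 3

    def __post_init__(self) -> None:
        if self.act_slope_mV <= 0 or self.inact_slope_mV <= 0:
            raise InvalidParameterError("Boltzmann slopes must be > 0")
        if min(self.tau_inact_0mV_ms, self.tau_rec_m80mV_ms, self.tau_act_ms) <= 0:
            raise InvalidParameterError("time constants must be > 0")
        if self.gmax_density < 0:
            raise InvalidParameterError("gmax_density must be >= 0")
        if int(self.gate_exponent) < 1:
            raise InvalidParameterError("gate_exponent must be >= 1")


def steady_state_gate(V, V12: float, slope: float,
                      direction: Literal["increasing", "decreasing"]):
    """Boltzmann steady-state curve, 1/(1+exp(±(V12-V)/slope)).

    ``increasing`` rises with depolarisation (activation), ``decreasing``
    falls (availability / fast inactivation).  Value is 0.5 at ``V == V12``.
    """
    if slope <= 0:
        raise InvalidParameterError("slope must be > 0")
    V = np.asarray(V, dtype=float)
    if direction == "increasing":
        z = (V12 - V) / slope
    elif direction == "decreasing":
        z = (V - V12) / slope
    else:
        raise InvalidParameterError(f"unknown direction {direction!r}")
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def _m_inf(V, p: GatingParams) -> np.ndarray:
    b = steady_state_gate(V, p.act_V12_mV, p.act_slope_mV, "increasing")
    return np.power(b, 1.0 / p.gate_exponent)


def _h_inf(V, p: GatingParams):
    return steady_state_gate(V, p.inact_V12_mV, p.inact_slope_mV, "decreasing")


def gate_time_constant(V, params: GatingParams,
                       gate: Literal["activation", "inactivation"]) -> float:
    """Voltage-dependent relaxation time constant of one gate, in ms.

    The inactivation constant passes exactly through the two measured anchors
    (``tau_inact_0mV_ms`` at 0 mV, ``tau_rec_m80mV_ms`` at -80 mV) with
    log-linear interpolation in between and clamping outside.  The activation
    constant is ``tau_act_ms`` at 0 mV with a mild bell around the activation
    midpoint.
    """
    V = float(np.asarray(V, dtype=float))
    if not -150.0 <= V <= 50.0:
        raise InvalidParameterError(f"voltage {V} mV outside [-150, 50]")
    if gate == "activation":
        def bell(v: float) -> float:
            return 0.55 + 0.45 * math.exp(-((v - params.act_V12_mV) / 50.0) ** 2)
        return params.tau_act_ms * bell(V) / bell(0.0)
    if gate == "inactivation":
        v = min(max(V, -80.0), 0.0)
        log_tau = (math.log(params.tau_rec_m80mV_ms)
                   + (v + 80.0) / 80.0
                   * (math.log(params.tau_inact_0mV_ms)
                      - math.log(params.tau_rec_m80mV_ms)))
        return math.exp(log_tau)
    raise InvalidParameterError(f"unknown gate {gate!r}")


# ---------------------------------------------------------------------------
# sweep simulation


def _check_accuracy(protocol: VoltageProtocol, params: GatingParams) -> None:
    dt = protocol.sample_interval_ms
    voltages = {float(protocol.holding_mV)}
    for i in range(protocol.n_sweeps):
        for _, v, _ in protocol.resolved_epochs(i):
            voltages.add(v)
    tau_min = min(min(gate_time_constant(v, params, "activation"),
                      gate_time_constant(v, params, "inactivation"))
                  for v in voltages)
    if dt > tau_min / 5.0:
        raise SimulationAccuracyError(
            f"sample interval {dt} ms too coarse for fastest time constant "
            f"{tau_min:.3f} ms (needs dt <= tau/5)")


def simulate_sweep(params: GatingParams, capacitance_pF: float,
                   protocol: VoltageProtocol, sweep_index: int,
                   noise_sd_pA: float = 0.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate one sweep; returns the current trace in pA on the sample grid.

    Gating state starts at equilibrium for the holding voltage.  Within each
    epoch the gates relax exponentially in closed form and the current is
    ``gmax_density * C * m**p * h * (V - E_rev)`` (inward negative) plus
    additive Gaussian noise.
    """
    if not 0 <= sweep_index < protocol.n_sweeps:
        raise IndexError(f"sweep_index {sweep_index} out of range")
    _check_accuracy(protocol, params)
    dt = protocol.sample_interval_ms
    p = int(params.gate_exponent)
    gmax = params.gmax_density * capacitance_pF  # nS

    m = float(_m_inf(protocol.holding_mV, params))
    h = float(_h_inf(protocol.holding_mV, params))
    chunks = []
    for _, V, n in protocol.epoch_samples(sweep_index):
        if n > 0:
            mi, hi = float(_m_inf(V, params)), float(_h_inf(V, params))
            tm = gate_time_constant(V, params, "activation")
            th = gate_time_constant(V, params, "inactivation")
            t = np.arange(n) * dt
            mt = mi + (m - mi) * np.exp(-t / tm)
            ht = hi + (h - hi) * np.exp(-t / th)
            chunks.append(gmax * mt**p * ht * (V - params.E_rev_mV))
            # advance state to the end of the epoch (exact)
            m = mi + (m - mi) * math.exp(-n * dt / tm)
            h = hi + (h - hi) * math.exp(-n * dt / th)
    trace = np.concatenate(chunks) if chunks else np.zeros(0)
    if noise_sd_pA > 0:
        if rng is None:
            raise InvalidParameterError("rng required when noise_sd_pA > 0")
        trace = trace + rng.normal(0.0, noise_sd_pA, trace.shape)
    return trace


# ---------------------------------------------------------------------------
# cells and cohorts


@dataclass
class SweepRecording:
    """Sweep matrix (time x sweep, pA) of one protocol for one cell."""

    protocol: VoltageProtocol
    data: np.ndarray  # shape (n_samples, n_sweeps)

    def __post_init__(self) -> None:
        expected = (self.protocol.n_samples(0), self.protocol.n_sweeps)
        if self.data.shape != expected:
            raise InvalidParameterError(
                f"sweep matrix shape {self.data.shape} != {expected}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("current values must be finite")


@dataclass
class CellRecording:
    """All recorded protocols plus metadata for one cell."""

    cell_id: str
    variant_id: str
    capacitance_pF: float
    series_resistance_MOhm: float
    recordings: dict[str, SweepRecording] = field(default_factory=dict)


@dataclass
class PopulationSpec:
    """Recipe for a cohort of virtual cells expressing one channel variant.

    ``param_means`` are the cohort-mean gating parameters; ``param_cv`` maps
    GatingParams field names to coefficients of variation (SD relative to
    |mean|).  Positive-definite quantities (conductance, slopes, time
    constants) are drawn log-normally, voltages normally.  ``n_recovery``
    limits how many cells receive the recovery protocol (the study recorded it
    in a subset of cells); ``None`` means all.
    """

    variant_id: str
    n_cells: int
    param_means: GatingParams
    param_cv: Mapping[str, float] = field(default_factory=dict)
    capacitance_pF: tuple[float, float] = (15.0, 4.5)
    series_resistance_MOhm: tuple[float, float] = (0.8, 0.25)
    noise_sd_pA: float = 10.0
    seed: int = 0
    n_recovery: int | None = None
    observable_means: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise InvalidParameterError("n_cells must be >= 0")
        if any(cv < 0 for cv in self.param_cv.values()):
            raise InvalidParameterError("coefficients of variation must be >= 0")
        if self.capacitance_pF[0] <= 0:
            raise InvalidParameterError("capacitance mean must be > 0")


_LOGNORMAL_FIELDS = {"gmax_density", "act_slope_mV", "inact_slope_mV",
                     "tau_inact_0mV_ms", "tau_rec_m80mV_ms", "tau_act_ms"}
_NORMAL_FIELDS = {"act_V12_mV", "inact_V12_mV", "E_rev_mV"}


def _draw_params(spec: PopulationSpec, rng: np.random.Generator,
                 log) -> GatingParams:
    """One cell's gating parameters drawn around the cohort means."""
    updates: dict[str, float] = {}
    for name, cv in spec.param_cv.items():
        if cv == 0:
            continue
        mean = getattr(spec.param_means, name)
        if name in _LOGNORMAL_FIELDS:
            # mean-preserving log-normal
            sigma2 = math.log1p(cv * cv)
            mu = math.log(abs(mean)) - sigma2 / 2.0
            updates[name] = math.copysign(
                rng.lognormal(mu, math.sqrt(sigma2)), mean)
        elif name in _NORMAL_FIELDS:
            updates[name] = rng.normal(mean, cv * abs(mean))
        else:
            raise InvalidParameterError(f"unknown parameter field {name!r}")
    for attempt in range(100):
        try:
            return replace(spec.param_means, **updates)
        except InvalidParameterError:
            # a draw violated positivity; redraw the offending fields
            log(f"{spec.variant_id}: invalid parameter draw, redrawing")
            for name in list(updates):
                if name in _LOGNORMAL_FIELDS:
                    continue
                mean = getattr(spec.param_means, name)
                updates[name] = rng.normal(mean, spec.param_cv[name] * abs(mean))
    raise InvalidParameterError("could not draw valid parameters")  # pragma: no cover


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     floor_frac: float = 0.05) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > floor_frac * mean:
            return x
    return floor_frac * mean


def simulate_cell(params: GatingParams, capacitance_pF: float,
                  series_resistance_MOhm: float,
                  protocols: Mapping[str, VoltageProtocol],
                  noise_sd_pA: float = 0.0,
                  rng: np.random.Generator | None = None,
                  cell_id: str = "cell", variant_id: str = "") -> CellRecording:
    """Simulate every sweep of every protocol for one cell."""
    recs = {}
    for name, proto in protocols.items():
        data = np.column_stack([
            simulate_sweep(params, capacitance_pF, proto, i,
                           noise_sd_pA=noise_sd_pA, rng=rng)
            for i in range(proto.n_sweeps)])
        recs[name] = SweepRecording(protocol=proto, data=data)
    return CellRecording(cell_id=cell_id, variant_id=variant_id,
                         capacitance_pF=capacitance_pF,
                         series_resistance_MOhm=series_resistance_MOhm,
                         recordings=recs)


def generate_cohort(spec: PopulationSpec,
                    protocols: Mapping[str, VoltageProtocol] | None = None,
                    log=None) -> tuple[list[CellRecording], pd.DataFrame]:
    """Simulate a cohort of cells and return recordings plus a truth table.

    The truth table has one row per cell with the drawn gating parameters,
    capacitance and series resistance.  When the population spec carries
    ``observable_means`` (targets in measurement space, e.g. set by the
    calibration layer), ``true_<param>`` columns give the expected measured
    value of each drawn cell: the draw corrected by the cohort-level offset
    between latent means and observable targets.

    Reproducible: all randomness derives from ``spec.seed``.
    """
    log = log or (lambda msg: None)
    if protocols is None:
        protocols = build_standard_protocols()
    rng = child_rng(spec.seed, spec.variant_id, "cohort")
    cells, rows = [], []
    n_rec = spec.n_cells if spec.n_recovery is None else min(
        spec.n_recovery, spec.n_cells)
    for i in range(spec.n_cells):
        params = _draw_params(spec, rng, log)
        cap = _positive_normal(rng, *spec.capacitance_pF)
        rs = _positive_normal(rng, *spec.series_resistance_MOhm)
        protos = dict(protocols)
        if i >= n_rec:
            protos.pop("recovery", None)
        cell_id = f"{spec.variant_id}_c{i:03d}"
        cell = simulate_cell(params, cap, rs, protos,
                             noise_sd_pA=spec.noise_sd_pA, rng=rng,
                             cell_id=cell_id, variant_id=spec.variant_id)
        cells.append(cell)
        row = {"cell_id": cell_id, "variant_id": spec.variant_id,
               "capacitance_pF": cap, "series_resistance_MOhm": rs,
               "has_recovery": i < n_rec}
        for name in ("gmax_density", "E_rev_mV", "act_V12_mV", "act_slope_mV",
                     "inact_V12_mV", "inact_slope_mV", "tau_inact_0mV_ms",
                     "tau_rec_m80mV_ms"):
            row[name] = getattr(params, name)
        if spec.observable_means is not None:
            _add_observable_truth(row, params, spec)
        rows.append(row)
    truth = pd.DataFrame(rows)
    return cells, truth


_OBS_TO_LATENT = {
    "act_V12_mV": "act_V12_mV",
    "act_Vslope_mV": "act_slope_mV",
    "inact_V12_mV": "inact_V12_mV",
    "inact_Vslope_mV": "inact_slope_mV",
    "tau_inact_0mV_ms": "tau_inact_0mV_ms",
    "tau_rec_ms": "tau_rec_m80mV_ms",
    "Ipeak_density_pA_per_pF": "gmax_density",
}
_ADDITIVE_OBS = {"act_V12_mV", "inact_V12_mV", "act_Vslope_mV", "inact_Vslope_mV"}


def _add_observable_truth(row: dict, params: GatingParams,
                          spec: PopulationSpec) -> None:
    """Expected measured value per parameter for one drawn cell.

    The calibration layer aligns cohort-mean latent parameters with the
    observable targets; per-cell draws inherit the same (locally constant)
    offset, applied additively for voltages/slopes and multiplicatively for
    positive quantities.
    """
    assert spec.observable_means is not None
    for obs, latent in _OBS_TO_LATENT.items():
        if obs not in spec.observable_means:
            continue
        target = spec.observable_means[obs]
        mean_latent = getattr(spec.param_means, latent)
        drawn = getattr(params, latent)
        if obs in _ADDITIVE_OBS:
            row[f"true_{obs}"] = drawn + (target - mean_latent)
        else:
            row[f"true_{obs}"] = drawn * (target / mean_latent)
    if "Ipeak_density_pA_per_pF" in (spec.observable_means or {}):
        row["true_Ipeak_0mV_pA"] = (
            row["true_Ipeak_density_pA_per_pF"] * row["capacitance_pF"])


def draw_biophysics(spec: PopulationSpec,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-cell *measured-parameter* rows directly, without traces.

    Fast path for statistical calibration studies (e.g. family-wise error-rate
    replicates): returns a table with the seven analysed parameters per cell,
    drawn from the same cell-to-cell distributions the trace simulator uses,
    with measurement noise neglected (it is small relative to the biological
    spread at the study's recording quality).
    """
    rng = rng or child_rng(spec.seed, spec.variant_id, "biophys")
    obs = dict(spec.observable_means or {})
    means = {
        "Ipeak_density_pA_per_pF": obs.get("Ipeak_density_pA_per_pF",
                                           -spec.param_means.gmax_density),
        "act_V12_mV": obs.get("act_V12_mV", spec.param_means.act_V12_mV),
        "act_Vslope_mV": obs.get("act_Vslope_mV", spec.param_means.act_slope_mV),
        "inact_V12_mV": obs.get("inact_V12_mV", spec.param_means.inact_V12_mV),
        "inact_Vslope_mV": obs.get("inact_Vslope_mV",
                                   spec.param_means.inact_slope_mV),
        "tau_inact_0mV_ms": obs.get("tau_inact_0mV_ms",
                                    spec.param_means.tau_inact_0mV_ms),
        "tau_rec_ms": obs.get("tau_rec_ms", spec.param_means.tau_rec_m80mV_ms),
    }
    cvs = {obs_name: spec.param_cv.get(latent, 0.0)
           for obs_name, latent in _OBS_TO_LATENT.items()}
    n = spec.n_cells
    out = {"variant_id": [spec.variant_id] * n}
    for name, mean in means.items():
        cv = cvs[name]
        if cv == 0:
            out[name] = np.full(n, mean)
        elif name in ("act_V12_mV", "inact_V12_mV"):
            out[name] = rng.normal(mean, cv * abs(mean), n)
        else:
            sigma2 = math.log1p(cv * cv)
            draws = rng.lognormal(math.log(abs(mean)) - sigma2 / 2.0,
                                  math.sqrt(sigma2), n)
            out[name] = np.copysign(draws, mean)
    df = pd.DataFrame(out)
    if spec.n_recovery is not None:
        df.loc[spec.n_recovery:, "tau_rec_ms"] = np.nan
    df["cell_id"] = [f"{spec.variant_id}_c{i:03d}" for i in range(n)]
    return df
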