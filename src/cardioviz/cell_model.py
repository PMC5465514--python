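"""Single-myocyte electrophysiology: currents, gating and the membrane ODE.

The membrane follows ``dVm/dt = -(I_ion + I_stim)/Cm`` with ``I_ion`` the
sum of the 12 TNNP06 currents (see :mod:`cardioviz._tnnp06`). Hodgkin-
Huxley gates are advanced with the Rush-Larsen exponential update

    n(t + dt) = n_inf - (n_inf - n(t)) * exp(-dt / tau_n),

which is exact while the rates are frozen; concentrations, the RyR
adaptation variable and Vm itself use forward Euler. Units are mV, ms and
pA/pF throughout.

Transmural heterogeneity (endo/mid/epi) enters through the I_to and I_Ks
conductances and the s-gate kinetics; right-ventricular epicardium
additionally scales I_Ks by 2 and I_to by 4 relative to the left ventricle.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass

import numpy as np

from . import _tnnp06 as tp
from ._kernel import NPAR, PAR_IDX, PAR_NAMES, step_cells
from ._rest_states import REST_STATES

__all__ = [
    "CellClass", "VentricleSide", "CellParameters", "CellState", "GateRates",
    "StimulusSchedule", "SingleCellTrace", "quiescent_state",
    "compute_ionic_currents", "step_gate_rush_larsen", "step_cell",
    "run_single_cell", "apd90",
]

#: default cell-integration step, ms
DEFAULT_DT = 0.02

#: conventional stimulus: 1 ms at -52 pA/pF (negative I_stim depolarizes
#: under dVm/dt = -(I_ion + I_stim)/Cm)
DEFAULT_STIM_AMPLITUDE = -52.0
DEFAULT_STIM_DURATION = 1.0


class CellClass(enum.Enum):
    """Transmural myocyte class."""
    ENDO = "endo"
    MID = "mid"
    EPI = "epi"


class VentricleSide(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class GateRates:
    """Opening/closing rates of one Hodgkin-Huxley gate at fixed Vm.

    ``n_inf`` and ``tau_n`` are always derived from alpha and beta, never
    stored, so they cannot go stale.
    """
    alpha: float  # 1/ms
    beta: float   # 1/ms

    @property
    def n_inf(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def tau_n(self) -> float:
        return 1.0 / (self.alpha + self.beta)

    @classmethod
    def from_steady_tau(cls, n_inf: float, tau_n: float) -> "GateRates":
        if tau_n <= 0:
            raise ValueError(f"tau_n must be positive, got {tau_n}")
        return cls(alpha=n_inf / tau_n, beta=(1.0 - n_inf) / tau_n)


@dataclass(frozen=True)
class CellParameters:
    """Maximal conductances/permeabilities (nS/pF except g_CaL) and Cm.

    ``rv_scaling`` is the (I_Ks factor, I_to factor) pair applied to
    right-ventricular epicardial cells.
    """
    Cm: float = 1.0  # membrane capacitance per unit area (normalized, pF/pF)
    g_Na: float = tp.G_NA
    g_K1: float = tp.G_K1
    g_to: float = tp.G_TO["epi"]
    g_Kr: float = tp.G_KR
    g_Ks: float = tp.G_KS["epi"]
    g_CaL: float = tp.G_CAL
    k_NaCa: float = tp.KNACA
    P_NaK: float = tp.P_NAK
    g_pCa: float = tp.G_PCA
    g_pK: float = tp.G_PK
    g_bCa: float = tp.G_BCA
    g_bNa: float = tp.G_BNA
    rv_scaling: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self):
        for name in PAR_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")

    @classmethod
    def for_class(cls, cell_class: CellClass = CellClass.EPI, **overrides) -> "CellParameters":
        """Defaults with the class-dependent I_to/I_Ks densities filled in."""
        base = dict(g_to=tp.G_TO[cell_class.value], g_Ks=tp.G_KS[cell_class.value])
        base.update(overrides)
        return cls(**base)

    def effective(self, cell_class: CellClass, side: VentricleSide) -> dict[str, float]:
        """Conductance dict with RV-epicardial I_Ks/I_to scaling applied."""
        g = {name: float(getattr(self, name)) for name in PAR_NAMES}
        if side is VentricleSide.RIGHT and cell_class is CellClass.EPI:
            ks_fac, to_fac = self.rv_scaling
            g["g_Ks"] *= ks_fac
            g["g_to"] *= to_fac
        return g


GATE_NAMES = tp.RL_GATES + ("fcass", "rbar")
CONCENTRATION_NAMES = ("Cai", "CaSR", "CaSS", "Nai", "Ki")


@dataclass
class CellState:
    """Full state of one myocyte.

    gates maps gate name -> value in [0, 1]; concentrations maps ion-pool
    name -> mM (strictly positive).
    """
    Vm: float
    gates: dict[str, float]
    concentrations: dict[str, float]
    cell_class: CellClass = CellClass.EPI
    ventricle_side: VentricleSide = VentricleSide.LEFT

    def to_array(self) -> np.ndarray:
        """Pack into the (NVAR, 1) layout of the integrators."""
        S = np.empty((tp.NVAR, 1), dtype=np.float64)
        S[tp.IDX["Vm"], 0] = self.Vm
        for name in GATE_NAMES:
            S[tp.IDX[name], 0] = self.gates[name]
        for name in CONCENTRATION_NAMES:
            S[tp.IDX[name], 0] = self.concentrations[name]
        return S

    @classmethod
    def from_array(cls, S: np.ndarray, cell_class: CellClass = CellClass.EPI,
                   ventricle_side: VentricleSide = VentricleSide.LEFT) -> "CellState":
        S = np.asarray(S, dtype=np.float64).reshape(tp.NVAR, -1)
        return cls(
            Vm=float(S[tp.IDX["Vm"], 0]),
            gates={name: float(S[tp.IDX[name], 0]) for name in GATE_NAMES},
            concentrations={name: float(S[tp.IDX[name], 0]) for name in CONCENTRATION_NAMES},
            cell_class=cell_class,
            ventricle_side=ventricle_side,
        )

    def validate(self) -> None:
        """Raise ValueError naming the first non-finite/out-of-range component."""
        if not math.isfinite(self.Vm):
            raise ValueError(f"non-finite state component: Vm = {self.Vm}")
        for name, val in self.gates.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite state component: gate {name} = {val}")
        for name, val in self.concentrations.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite state component: concentration {name} = {val}")
            if val <= 0:
                raise ValueError(f"concentration {name} must be > 0, got {val}")


def quiescent_state(cell_class: CellClass = CellClass.EPI,
                    ventricle_side: VentricleSide = VentricleSide.LEFT) -> CellState:
    """Packaged quiescent (40 s pre-relaxed, unstimulated) state per class."""
    S = np.array(REST_STATES[cell_class.value], dtype=np.float64).reshape(tp.NVAR, 1)
    return CellState.from_array(S, cell_class, ventricle_side)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_ionic_currents(state: CellState, params: CellParameters):
    """Total I_ion (pA/pF) plus the 12 individual currents for inspection.

    Returns ``(I_ion, currents)`` where ``currents`` maps the names of
    :data:`cardioviz._tnnp06.CURRENT_NAMES` to floats.
    """
    state.validate()
    g = params.effective(state.cell_class, state.ventricle_side)
    S = state.to_array()
    cur = tp.ionic_currents(S, g)
    currents = {name: float(cur[name][0]) for name in tp.CURRENT_NAMES}
    return sum(currents.values()), currents


def step_gate_rush_larsen(gate_value: float, rates: GateRates, dt: float) -> float:
    """One Rush-Larsen update of a gate; exact for rates frozen over dt."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    tau = rates.tau_n
    if tau <= 0:
        raise ValueError(f"rates must be positive (tau_n = {tau})")
    n_inf = rates.n_inf
    return n_inf - (n_inf - gate_value) * math.exp(-dt / tau)


def step_cell(state: CellState, params: CellParameters, I_stim: float,
              dt: float = DEFAULT_DT, max_dt: float = DEFAULT_DT) -> CellState:
    """Advance one myocyte by ``dt``; returns a new state, input untouched."""
    if dt > max_dt + 1e-12:
        raise ValueError(
            f"dt = {dt} ms exceeds the configured cell-integration step {max_dt} ms")
    state.validate()
    g = params.effective(state.cell_class, state.ventricle_side)
    S = state.to_array()
    is_endo = np.array([state.cell_class is CellClass.ENDO])
    S2 = tp.step_states_numpy(S, g, is_endo, I_stim, dt, Cm=params.Cm)
    new_vm = S2[tp.IDX["Vm"], 0]
    if not np.isfinite(new_vm):
        raise FloatingPointError(
            f"Vm became non-finite in step_cell (dt={dt}, from Vm={state.Vm})")
    return CellState.from_array(S2, state.cell_class, state.ventricle_side)


@dataclass(frozen=True)
class StimulusSchedule:
    """Timed square current pulses for a single cell.

    Each event is (onset_ms, duration_ms, amplitude_pA_per_pF); negative
    amplitude depolarizes.
    """
    events: tuple[tuple[float, float, float], ...] = ()

    @classmethod
    def pacing(cls, cycle_length: float, n_beats: int, start: float = 0.0,
               duration: float = DEFAULT_STIM_DURATION,
               amplitude: float = DEFAULT_STIM_AMPLITUDE) -> "StimulusSchedule":
        return cls(tuple((start + k * cycle_length, duration, amplitude)
                         for k in range(n_beats)))

    def current_at(self, t: float) -> float:
        for onset, dur, amp in self.events:
            if onset <= t < onset + dur:
                return amp
        return 0.0


@dataclass
class SingleCellTrace:
    """Uniformly sampled Vm trace plus the terminal state."""
    time: np.ndarray            # ms
    Vm: np.ndarray              # mV
    currents: dict[str, np.ndarray] | None
    final_state: CellState

    def upstroke_count(self, threshold: float = 0.0) -> int:
        """Number of upward crossings of ``threshold`` (AP detection)."""
        above = self.Vm >= threshold
        return int(np.sum(above[1:] & ~above[:-1]))

    def save_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            names = list(self.currents) if self.currents else []
            w.writerow(["time_ms", "Vm_mV"] + names)
            for k in range(len(self.time)):
                row = [f"{self.time[k]:.6g}", f"{self.Vm[k]:.9g}"]
                row += [f"{self.currents[n][k]:.9g}" for n in names]
                w.writerow(row)

    def save_npz(self, path) -> None:
        """Binary table: time/Vm (and currents, if recorded) as an .npz."""
        cols = {"time_ms": self.time, "Vm_mV": self.Vm}
        if self.currents:
            cols.update(self.currents)
        np.savez(path, **cols)


def run_single_cell(params: CellParameters | None = None,
                    protocol: StimulusSchedule | None = None,
                    duration: float = 1000.0,
                    dt: float = DEFAULT_DT,
                    output_interval: float = 1.0,
                    initial_state: CellState | None = None,
                    record_currents: bool = False) -> SingleCellTrace:
    """Integrate one myocyte and sample its Vm at ``output_interval``.

    A zero ``duration`` yields a single sample: the initial state.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    state0 = initial_state or quiescent_state()
    if params is None:
        params = CellParameters.for_class(state0.cell_class)
    protocol = protocol or StimulusSchedule()
    state0.validate()

    g = params.effective(state0.cell_class, state0.ventricle_side)
    S = np.ascontiguousarray(state0.to_array())
    P = np.empty((NPAR, 1), dtype=np.float64)
    for name, row in PAR_IDX.items():
        P[row, 0] = g[name]
    is_endo = np.array([state0.cell_class is CellClass.ENDO], dtype=np.uint8)
    ext = np.zeros(1)
    istim = np.zeros(1)

    n_steps = int(round(duration / dt))
    out_every = max(1, int(round(output_interval / dt)))
    n_out = n_steps // out_every + 1
    times = np.empty(n_out)
    vms = np.empty(n_out)
    cur_store = {name: np.empty(n_out) for name in tp.CURRENT_NAMES} if record_currents else None

    def record(k_out, t):
        times[k_out] = t
        vms[k_out] = S[tp.IDX["Vm"], 0]
        if cur_store is not None:
            cur = tp.ionic_currents(S, g)
            for name in tp.CURRENT_NAMES:
                cur_store[name][k_out] = cur[name][0]

    record(0, 0.0)
    k_out = 1
    for k in range(n_steps):
        t = k * dt
        istim[0] = protocol.current_at(t)
        step_cells(S, P, is_endo, istim, ext, dt, params.Cm)
        if (k + 1) % out_every == 0:
            record(k_out, (k + 1) * dt)
            k_out += 1
    if not np.isfinite(S[tp.IDX["Vm"], 0]):
        raise FloatingPointError("Vm became non-finite during run_single_cell")
    return SingleCellTrace(
        time=times, Vm=vms, currents=cur_store,
        final_state=CellState.from_array(S, state0.cell_class, state0.ventricle_side),
    )


def apd90(trace: SingleCellTrace) -> float:
    """Action-potential duration at 90% repolarization of the first AP, ms.

    Measured from the maximum-upstroke sample to the first return below
    Vrest + 0.1 * amplitude.
    """
    vm = trace.Vm
    t = trace.time
    v_rest = vm[0]
    peak_idx = int(np.argmax(vm))
    v_peak = vm[peak_idx]
    if v_peak < 0:
        raise ValueError("no action potential in trace (peak below 0 mV)")
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    upstroke_idx = int(np.argmax(np.diff(vm[: peak_idx + 1])) ) if peak_idx > 0 else 0
    below = np.nonzero(vm[peak_idx:] <= v90)[0]
    if below.size == 0:
        raise ValueError("trace ends before 90% repolarization")
    return float(t[peak_idx + below[0]] - t[upstroke_idx])
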