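"""Passive dendritic voltage and the somatic integrator for sequence selectivity.

The soma is a leaky integrative unit coupled one-way to the terminal
dendritic compartment through an axial resistance:

    du_soma/dt = (1/tau) [ (u_rest - u_soma)
                           + (R_soma/R_s,axial) (u_dend(x0) - u_soma) ]

with u_rest = -70 mV, tau = R_soma C_soma = 22 ms and R_soma/R_s,axial = 5.
There is no feedback from the soma to the dendrite (no backpropagation).

The dendritic voltage itself is a passive compartmental cable (leak toward
rest, nearest-neighbour axial coupling with electrotonic space constant
``space_constant``, sealed ends), driven at spine segments by the synaptic
current waveform scaled by the spine's weight:

    du_i/dt = (u_rest - u_i)/tau_m
              + (space_constant^2 / (tau_m dx^2)) (u_{i+1} - 2 u_i + u_{i-1})
              + syn_amp * w_j * I_j(t) / (I0 tau_d)     [at spine segments]

so each presynaptic spike deposits ``syn_amp * w_j`` mV of depolarization
before leak and spread.  The cable equation, conductance amplitude and axial
parameters are not constrained by the calcium model; they are configuration
with defaults calibrated to give subthreshold responses before learning.
The synaptic electrical drive scales with the weight w, while the calcium
influx does not.

Both soma and cable are advanced with backward Euler (cable first, then the
soma using the updated terminal voltage).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .calcium_solver import SolverConfig, simulate
from .model_core import Geometry, InvalidParameterError, ModelParameters, SpineArrangement
from .plasticity import ConfigurationError
from .stimulation import StimulationProtocol, paired_timing


@dataclass(frozen=True)
class SomaParams:
    """Somatic integrator parameters."""

    u_rest: float = -70.0          # mV
    tau: float = 0.022             # membrane time constant, s
    R_ratio: float = 5.0           # R_soma / R_s,axial
    spike_threshold: float = -54.0  # mV (calibrated; threshold line only)

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.R_ratio <= 0:
            raise InvalidParameterError("tau and R_ratio must be positive")


@dataclass(frozen=True)
class CableParams:
    """Passive-cable parameters (all calibrated configuration)."""

    tau_m: float = 0.022           # membrane time constant, s
    space_constant: float = 30.0   # electrotonic length, um
    syn_amp: float = 1600.0        # mV of deposited depolarization per spike at w=1

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.space_constant <= 0:
            raise InvalidParameterError("tau_m and space_constant must be positive")


@dataclass
class CableState:
    """Dendritic and somatic membrane potential (mV) at time t (s)."""

    u_dend: np.ndarray
    u_soma: float
    t: float = 0.0

    def __post_init__(self) -> None:
        self.u_dend = np.asarray(self.u_dend, dtype=float)
        if not np.all(np.isfinite(self.u_dend)) or not np.isfinite(self.u_soma):
            raise InvalidParameterError("voltages must be finite")

    @classmethod
    def resting(cls, geometry: Geometry, soma: SomaParams) -> "CableState":
        return cls(u_dend=np.full(geometry.n_segments, soma.u_rest),
                   u_soma=soma.u_rest)


def step_soma(u_soma: float, u_dend_terminal: float, dt: float,
              params: SomaParams) -> float:
    """One backward-Euler step of the somatic integrator."""
    if dt >= params.tau:
        raise ConfigurationError("dt must be smaller than the soma time constant")
    a = dt / params.tau
    return (u_soma + a * (params.u_rest + params.R_ratio * u_dend_terminal)) / (
        1.0 + a * (1.0 + params.R_ratio))


class CableSolver:
    """Pre-factorized backward-Euler integrator for the passive cable + soma.

    The soma reads the voltage of segment 0 (the terminal compartment).
    """

    def __init__(self, arrangement: SpineArrangement, dt: float,
                 cable: CableParams | None = None,
                 soma: SomaParams | None = None):
        self.arrangement = arrangement
        self.cable = cable or CableParams()
        self.soma = soma or SomaParams()
        self.dt = dt
        geom = arrangement.geometry
        n = geom.n_segments
        k_ax = self.cable.space_constant ** 2 / (self.cable.tau_m * geom.dx ** 2)
        A = np.zeros((n, n))
        idx = np.arange(n)
        A[idx, idx] = -1.0 / self.cable.tau_m - 2.0 * k_ax
        A[idx[:-1], idx[:-1] + 1] = k_ax
        A[idx[1:], idx[1:] - 1] = k_ax
        A[0, 0] += k_ax          # sealed ends
        A[n - 1, n - 1] += k_ax
        self._lu = scipy.linalg.lu_factor(np.eye(n) - dt * A, check_finite=False)

    def step(self, state: CableState, drive: np.ndarray) -> CableState:
        """Advance one dt.  ``drive`` is the per-segment input in mV/s."""
        rest = self.soma.u_rest / self.cable.tau_m
        rhs = state.u_dend + self.dt * (rest + drive)
        u_new = scipy.linalg.lu_solve(self._lu, rhs, check_finite=False)
        if not np.all(np.isfinite(u_new)) or np.abs(u_new).max() > 1e4:
            raise ConfigurationError("cable voltage diverged; check parameters")
        u_soma = step_soma(state.u_soma, u_new[0], self.dt, self.soma)
        return CableState(u_dend=u_new, u_soma=u_soma, t=state.t + self.dt)


def step_cable(state: CableState, synaptic_drive: np.ndarray, dt: float,
               arrangement: SpineArrangement,
               cable_params: CableParams | None = None,
               soma_params: SomaParams | None = None) -> CableState:
    """One cable+soma step (convenience wrapper building a solver).

    ``synaptic_drive`` is the per-spine weight-scaled input, already in mV/s;
    it is deposited at each spine's segment.
    """
    solver = CableSolver(arrangement, dt, cable_params, soma_params)
    drive = np.zeros(arrangement.geometry.n_segments)
    for j, seg in enumerate(arrangement.spine_segments):
        drive[seg] += synaptic_drive[j]
    return solver.step(state, drive)


def run_voltage(protocol: StimulationProtocol, arrangement: SpineArrangement,
                weights: np.ndarray, params: ModelParameters, T: float,
                dt: float = 1e-4, cable: CableParams | None = None,
                soma: SomaParams | None = None,
                store_every: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the voltage response to a protocol with frozen weights.

    Returns (times, u_soma trace).  The synaptic current of each spine is the
    same exponential train that drives calcium influx, scaled by the spine's
    weight.
    """
    cable = cable or CableParams()
    soma = soma or SomaParams()
    solver = CableSolver(arrangement, dt, cable, soma)
    m = arrangement.n_spines
    state = CableState.resting(arrangement.geometry, soma)
    # normalized current state per spine (I/I0), exact between-step decay
    cur = np.zeros(m)
    decay = np.exp(-dt / params.tau_d)
    jumps: dict[int, list[tuple[int, float]]] = {}
    for j in range(m):
        for ts in protocol.times_for(j):
            k_fold = int(np.ceil(ts / dt - 1e-9))
            jumps.setdefault(k_fold, []).append(
                (j, np.exp(-(k_fold * dt - ts) / params.tau_d)))
    n_steps = int(round(T / dt))
    gain = cable.syn_amp / params.tau_d  # mV/s per unit (w * I/I0)
    seg_of = np.asarray(arrangement.spine_segments, dtype=int)
    times, u_soma = [state.t], [state.u_soma]
    drive = np.zeros(arrangement.geometry.n_segments)
    for k in range(n_steps):
        for j, amp in jumps.get(k, ()):
            cur[j] += amp
        drive[:] = 0.0
        np.add.at(drive, seg_of, gain * np.asarray(weights) * cur)
        state = solver.step(state, drive)
        cur *= decay
        if (k + 1) % store_every == 0 or k == n_steps - 1:
            times.append(state.t)
            u_soma.append(state.u_soma)
    return np.asarray(times), np.asarray(u_soma)


@dataclass
class SequenceReport:
    """Outcome of a sequence-selectivity experiment."""

    learned_order: str                    # "inward" | "outward" | "none"
    peaks: dict                           # order -> peak u_soma (mV)
    responses: dict                       # order -> peak depolarization above rest (mV)
    ratio: float                          # learned vs non-learned response
    crossed_threshold: dict               # order -> bool
    weights_after_learning: list
    u_rest: float
    spike_threshold: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def sequence_arrangement(dx: float = 0.5, length: float = 20.0,
                         proximal_um: float = 5.25, distance: float = 1.0,
                         weights: tuple[float, float] = (0.5, 0.5),
                         ) -> SpineArrangement:
    """Two spines ``distance`` apart, proximal one ~5 um from the soma end.

    The soma attaches at x = 0.  Spine 0 is proximal, spine 1 distal.
    """
    geom = Geometry.from_length(length, dx)
    i_prox = int(round(proximal_um / dx - 0.5))
    i_dist = i_prox + int(round(distance / dx))
    return SpineArrangement(geometry=geom, spine_segments=(i_prox, i_dist),
                            groups=("plain", "plain"), initial_weights=weights)


def sequence_experiment(order: str, learn_reps: int = 5,
                        arrangement: SpineArrangement | None = None,
                        params: ModelParameters | None = None,
                        inter_input: float = 0.1,
                        plasticity: bool = True,
                        dt: float = 1e-4,
                        cable: CableParams | None = None,
                        soma: SomaParams | None = None) -> SequenceReport:
    """Learn one input order, then test both orders with frozen weights.

    ``order`` is "inward" (distal spine first, activation travelling toward
    the soma), "outward" (proximal first) or "none" (skip learning, passive
    baseline).  Learning runs the calcium + plasticity dynamics for
    ``learn_reps`` presentations of the sequence with inter-input interval
    ``inter_input`` (s); the test phase presents each order once with
    plasticity frozen and reports the peak somatic potential.
    """
    if order not in ("inward", "outward", "none"):
        raise InvalidParameterError(f"unknown order {order!r}")
    arrangement = arrangement or sequence_arrangement()
    if arrangement.n_spines != 2:
        raise InvalidParameterError("sequence experiment needs exactly two spines")
    params = params or ModelParameters()
    soma = soma or SomaParams()
    prox, dist = 0, 1

    def seq_protocol(o: str, reps: int) -> StimulationProtocol:
        first, second = (dist, prox) if o == "inward" else (prox, dist)
        return paired_timing(first, second, inter_input, repetitions=reps)

    weights = np.asarray(arrangement.initial_weights, dtype=float)
    if plasticity and order != "none":
        proto = seq_protocol(order, learn_reps)
        res = simulate(proto, arrangement, params, T=proto.end_time + 0.5,
                       cfg=SolverConfig(dt=dt, store_every=10 ** 9))
        weights = res.final_weights

    peaks, responses, crossed = {}, {}, {}
    for o in ("inward", "outward"):
        proto = seq_protocol(o, 1)
        _, u = run_voltage(proto, arrangement, weights, params,
                           T=proto.end_time + 0.3, dt=dt, cable=cable, soma=soma)
        peaks[o] = float(u.max())
        responses[o] = float(u.max() - soma.u_rest)
        crossed[o] = bool(u.max() > soma.spike_threshold)

    if order == "none":
        ratio = 1.0
    else:
        other = "outward" if order == "inward" else "inward"
        num, den = responses[order], responses[other]
        ratio = 1.0 if num == den == 0.0 else float(num / den) if den else float("inf")
    return SequenceReport(
        learned_order=order, peaks=peaks, responses=responses, ratio=ratio,
        crossed_threshold=crossed,
        weights_after_learning=[float(w) for w in weights],
        u_rest=soma.u_rest, spike_threshold=soma.spike_threshold)
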