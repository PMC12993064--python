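"""Backward-Euler integration of the coupled dendrite/spine calcium system.

Dendritic shaft (per segment, concentration C_d in uM):

    dC_d/dt = D d2C_d/dx2 - k_d C_d [spine] + k_s C_s [spine] - C_d/tau_decay

Spine heads (per spine):

    dC_s/dt = J_syn + k_d C_d - k_s C_s - C_s/tau_decay

with J_syn = gamma * I_ext / (z F V_s) and
I_ext(t) = sum_i I0 exp(-(t - t_i)/tau_d) H(t - t_i).

The coupled (C_d, C_s) vector is advanced with an implicit (backward) Euler
step in which diffusion, leak and both exchange fluxes are treated
implicitly; the synaptic influx is evaluated at the step start, keeping the
system matrix constant so it can be LU-factorized once per run.  The matrix
is an M-matrix, so concentrations remain non-negative at every step.

By default the exchange fluxes enter both equations with identical magnitude
in concentration units ("plain" flux mode).  Because the two compartments
have different volumes this does not conserve moles across the neck; the
optional "volume-corrected" mode rescales transferred amounts by the volume
ratio so that they do.

Boundary conditions are reflecting (no-flux) at both cable ends.  Internal
units: s, um, uM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .model_core import (InvalidParameterError, ModelParameters,
                         SpineArrangement, compartment_volumes, coupling_rates)
from .plasticity import ConfigurationError, update_weights
from .stimulation import StimulationProtocol

FLUX_MODES = ("plain", "volume-corrected")


@dataclass
class SolverConfig:
    """Numerical settings for the backward-Euler integrator.

    dt defaults to 0.05 ms (a fifth of the shortest intrinsic timescale is
    the hard ceiling, enforced against tau_d at solver construction);
    store_every decimates the recorded time series.
    """

    dt: float = 5e-5
    scheme: str = "backward-euler"
    boundary: str = "no-flux"
    store_every: int = 20
    flux_mode: str = "plain"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.scheme != "backward-euler":
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.boundary != "no-flux":
            raise ConfigurationError(f"unknown boundary {self.boundary!r}")
        if self.store_every < 1:
            raise ConfigurationError("store_every must be >= 1")
        if self.flux_mode not in FLUX_MODES:
            raise ConfigurationError(f"flux_mode must be one of {FLUX_MODES}")


@dataclass
class CalciumState:
    """Calcium concentrations (uM) of all compartments at time t (s)."""

    C_d: np.ndarray
    C_s: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.C_d = np.asarray(self.C_d, dtype=float)
        self.C_s = np.asarray(self.C_s, dtype=float)
        if np.any(self.C_d < 0) or np.any(self.C_s < 0):
            raise InvalidParameterError("concentrations must be non-negative")

    @classmethod
    def zeros(cls, arrangement: SpineArrangement, t: float = 0.0) -> "CalciumState":
        return cls(C_d=np.zeros(arrangement.geometry.n_segments),
                   C_s=np.zeros(arrangement.n_spines), t=t)


def synaptic_current(t, spike_times, I0: float, tau_d: float):
    """I_ext(t) in pA: sum of exponentially decaying kernels over past spikes."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    for ti in np.asarray(spike_times, dtype=float):
        dt = t - ti
        out += np.where(dt >= 0, I0 * np.exp(-np.minimum(dt, 700 * tau_d) / tau_d), 0.0)
    return out if out.ndim else float(out)


def current_to_concentration_rate(I_pA: float, volume_um3: float,
                                  z: float, F: float) -> float:
    """Convert a calcium-carrying current (pA) into uM/s in a given volume.

    pA -> C/s is 1e-12; division by z*F (C/mol) gives mol/s; division by the
    volume in litres (um^3 -> L is 1e-15) gives mol/L/s; M -> uM is 1e6.
    The net factor is 1e9.
    """
    if volume_um3 <= 0:
        raise InvalidParameterError("volume must be positive")
    return 1e9 * I_pA / (z * F * volume_um3)


def synaptic_calcium_flux(I_pA: float, params: ModelParameters) -> float:
    """J_syn (uM/s) into a spine head for a synaptic current I (pA)."""
    _, V_s = compartment_volumes(params, dx=1.0)
    return current_to_concentration_rate(params.gamma * I_pA, V_s,
                                         params.z, params.F)


def build_system_matrix(arrangement: SpineArrangement, params: ModelParameters,
                        flux_mode: str = "plain") -> np.ndarray:
    """Dense generator matrix A of the linear system dc/dt = A c + b(t).

    Unknown ordering: n_segments dendritic concentrations followed by
    n_spines spine concentrations.
    """
    geom = arrangement.geometry
    n, m = geom.n_segments, arrangement.n_spines
    dx = geom.dx
    A = np.zeros((n + m, n + m))

    alpha = params.D / dx ** 2
    idx = np.arange(n)
    A[idx, idx] -= 2.0 * alpha
    A[idx[:-1], idx[:-1] + 1] += alpha
    A[idx[1:], idx[1:] - 1] += alpha
    # Reflecting ends: the missing neighbour is mirrored.
    A[0, 0] += alpha
    A[n - 1, n - 1] += alpha

    leak = 1.0 / params.tau_decay
    A[np.arange(n + m), np.arange(n + m)] -= leak

    k_d, k_s = coupling_rates(params, dx) if params.D > 0 else (0.0, 0.0)
    V_d, V_s = compartment_volumes(params, dx)
    if flux_mode == "plain":
        sd_gain, ds_gain = 1.0, 1.0
    elif flux_mode == "volume-corrected":
        sd_gain, ds_gain = V_s / V_d, V_d / V_s  # mole-conserving transfer
    else:
        raise ConfigurationError(f"flux_mode must be one of {FLUX_MODES}")
    for j, seg in enumerate(arrangement.spine_segments):
        sj = n + j
        A[seg, seg] -= k_d
        A[seg, sj] += k_s * sd_gain
        A[sj, seg] += k_d * ds_gain
        A[sj, sj] -= k_s
    return A


class BackwardEulerSolver:
    """Pre-factorized implicit integrator for one arrangement/parameter set."""

    def __init__(self, arrangement: SpineArrangement, params: ModelParameters,
                 cfg: SolverConfig | None = None):
        self.arrangement = arrangement
        self.params = params
        self.cfg = cfg or SolverConfig()
        if self.cfg.dt > params.tau_d / 5 + 1e-15:
            raise ConfigurationError(
                f"dt={self.cfg.dt} must not exceed tau_d/5={params.tau_d / 5}")
        n = arrangement.geometry.n_segments
        m = arrangement.n_spines
        self._n, self._m = n, m
        A = build_system_matrix(arrangement, params, self.cfg.flux_mode)
        M = np.eye(n + m) - self.cfg.dt * A
        self._lu = scipy.linalg.lu_factor(M, check_finite=False)
        _, V_s = compartment_volumes(params, arrangement.geometry.dx)
        # uM/s per pA of synaptic current.
        self._j_per_pA = current_to_concentration_rate(
            params.gamma, V_s, params.z, params.F)

    def step(self, state: CalciumState, currents_pA: np.ndarray) -> CalciumState:
        """Advance one dt; ``currents_pA`` are per-spine synaptic currents."""
        rhs = np.concatenate([state.C_d, state.C_s])
        if self._m:
            rhs[self._n:] += self.cfg.dt * self._j_per_pA * np.asarray(currents_pA)
        sol = scipy.linalg.lu_solve(self._lu, rhs, check_finite=False)
        np.maximum(sol, 0.0, out=sol)  # clear roundoff-level negatives
        return CalciumState(C_d=sol[:self._n], C_s=sol[self._n:],
                            t=state.t + self.cfg.dt)


def step(state: CalciumState, inputs, arrangement: SpineArrangement,
         params: ModelParameters, cfg: SolverConfig | None = None) -> CalciumState:
    """One backward-Euler step (convenience wrapper building a solver)."""
    solver = BackwardEulerSolver(arrangement, params, cfg)
    return solver.step(state, np.asarray(inputs, dtype=float))


@dataclass
class SimulationResult:
    """Decimated time series plus final weight changes of one simulation."""

    times: np.ndarray            # (k,) s
    C_d: np.ndarray              # (k, n_segments) uM
    C_s: np.ndarray              # (k, n_spines) uM
    weights: np.ndarray          # (k, n_spines)
    arrangement: SpineArrangement
    params: ModelParameters
    cfg: SolverConfig
    protocol_label: str = ""

    @property
    def final_weights(self) -> np.ndarray:
        return self.weights[-1]

    @property
    def delta_w(self) -> np.ndarray:
        """Final minus initial weight, per spine."""
        return self.final_weights - np.asarray(self.arrangement.initial_weights)

    def group_delta_w(self, group: str) -> np.ndarray:
        return self.delta_w[self.arrangement.group_indices(group)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format tidy table: time, compartment, variable, value."""
        frames = []
        for j in range(self.C_d.shape[1]):
            frames.append(pd.DataFrame({
                "time_s": self.times, "compartment": f"seg{j}",
                "variable": "C_d", "value": self.C_d[:, j]}))
        for j in range(self.C_s.shape[1]):
            frames.append(pd.DataFrame({
                "time_s": self.times, "compartment": f"spine{j}",
                "variable": "C_s", "value": self.C_s[:, j]}))
            frames.append(pd.DataFrame({
                "time_s": self.times, "compartment": f"spine{j}",
                "variable": "w", "value": self.weights[:, j]}))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("C_d", data=self.C_d)
            f.create_dataset("C_s", data=self.C_s)
            f.create_dataset("weights", data=self.weights)
            meta = f.create_group("metadata")
            meta.attrs["protocol"] = self.protocol_label
            meta.attrs["arrangement_json"] = self.arrangement.to_json()
            for key, value in self.params.to_dict().items():
                meta.attrs[f"param_{key}"] = value
            for key, value in dataclasses.asdict(self.cfg).items():
                meta.attrs[f"cfg_{key}"] = value

    def summary(self) -> dict:
        """JSON-serializable run summary (deterministic key order)."""
        return {
            "protocol": self.protocol_label,
            "n_spines": self.arrangement.n_spines,
            "groups": list(self.arrangement.groups),
            "initial_weights": [round(float(w), 12)
                                for w in self.arrangement.initial_weights],
            "final_weights": [round(float(w), 12) for w in self.final_weights],
            "delta_w": [round(float(d), 12) for d in self.delta_w],
            "dt": self.cfg.dt,
            "dx": self.arrangement.geometry.dx,
            "flux_mode": self.cfg.flux_mode,
        }


def simulate(protocol: StimulationProtocol, arrangement: SpineArrangement,
             params: ModelParameters, T: float,
             cfg: SolverConfig | None = None, plasticity_on: bool = True,
             initial_state: CalciumState | None = None) -> SimulationResult:
    """Run the coupled calcium + weight dynamics for duration ``T`` (s).

    The synaptic current of each spine is propagated exactly between steps
    (it obeys dI/dt = -I/tau_d with jumps of I0 at spike times) and sampled
    at step starts.  Weights are updated once per step from the end-of-step
    spine calcium.
    """
    cfg = cfg or SolverConfig()
    for spine in protocol.spikes:
        if not 0 <= spine < arrangement.n_spines:
            raise InvalidParameterError(
                f"protocol references spine {spine} but arrangement has "
                f"{arrangement.n_spines}")
    if protocol.end_time > T:
        raise InvalidParameterError("protocol spike times must lie within [0, T]")

    solver = BackwardEulerSolver(arrangement, params, cfg)
    m = arrangement.n_spines
    state = initial_state or CalciumState.zeros(arrangement)
    weights = np.asarray(arrangement.initial_weights, dtype=float).copy()

    currents = np.zeros(m)
    decay = np.exp(-cfg.dt / params.tau_d)

    # Each spike is folded into the current at the first step start at or
    # after its time, attenuated by the decay accrued in between.
    jumps: dict[int, list[tuple[int, float]]] = {}
    for j in range(m):
        for ts in protocol.times_for(j):
            k_fold = int(np.ceil(ts / cfg.dt - 1e-9))
            amp = params.I0 * np.exp(-(k_fold * cfg.dt - ts) / params.tau_d)
            jumps.setdefault(k_fold, []).append((j, amp))

    n_steps = int(round(T / cfg.dt))
    rec_t, rec_cd, rec_cs, rec_w = [state.t], [state.C_d.copy()], \
        [state.C_s.copy()], [weights.copy()]

    for k in range(n_steps):
        for j, amp in jumps.get(k, ()):
            currents[j] += amp
        state = solver.step(state, currents)
        if plasticity_on and m:
            weights = update_weights(weights, state.C_s, cfg.dt, params)
        currents *= decay
        if (k + 1) % cfg.store_every == 0 or k == n_steps - 1:
            rec_t.append(state.t)
            rec_cd.append(state.C_d.copy())
            rec_cs.append(state.C_s.copy())
            rec_w.append(weights.copy())

    return SimulationResult(
        times=np.asarray(rec_t), C_d=np.asarray(rec_cd),
        C_s=np.asarray(rec_cs), weights=np.asarray(rec_w),
        arrangement=arrangement, params=params, cfg=cfg,
        protocol_label=protocol.label)
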