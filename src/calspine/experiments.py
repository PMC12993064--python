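"""Figure-level experiment drivers: timing windows, multi-spine frequency
regimes, and the diffusion-constant matching error.

All drivers are deterministic given their seeds; per-configuration seeds are
derived from a master seed through a counter so that increasing the number
of configurations never changes the earlier ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium_solver import SolverConfig, simulate
from .model_core import (ArrangementConfig, InvalidParameterError,
                         ModelParameters, SpineArrangement,
                         default_parameters, generate_arrangement,
                         two_spine_arrangement)
from .presets import EXPECTED_SIGN_PATTERNS, FREQUENCY_PRESETS
from .stimulation import frequency_protocol, paired_timing, triplet

#: |delta w| below this dead band counts as "no significant change".
DEAD_BAND = 0.01

GROUP_ORDER = ("Stim", "Un_in", "Un_out")

#: Calibrated initial weights of the two-spine demonstrations (unequal
#: initial spine states, cf. the randomly drawn weights of the multi-spine
#: protocols).
TWO_SPINE_WEIGHTS = (0.48, 0.30)


def config_seed(master_seed: int, k: int) -> int:
    """Counter-derived per-configuration seed (prefix-stable in k)."""
    return (master_seed * 100003 + k) % (2 ** 31)


# ---------------------------------------------------------------------------
# Two-spine demonstrations (competition / cooperation / timing reversal)
# ---------------------------------------------------------------------------

def two_spine_regimes(params: ModelParameters | None = None,
                      distance: float = 1.0,
                      weights: tuple[float, float] = TWO_SPINE_WEIGHTS,
                      dt: float = 1e-4) -> pd.DataFrame:
    """Run the three canonical two-spine protocols and report delta w.

    single spike -> homosynaptic potentiation with heterosynaptic depression
    (competition); burst -> both potentiate (cooperation); +15 ms pairing ->
    depression at the leading spine, potentiation at the trailing one.
    """
    from .stimulation import burst, single_spike

    params = params or default_parameters("fig2")
    arr = two_spine_arrangement(distance=distance, weights=weights)
    cfg = SolverConfig(dt=dt, store_every=10 ** 9)
    rows = []
    for name, proto in [("single_spike", single_spike(0)),
                        ("burst", burst(0)),
                        ("paired_+15ms", paired_timing(0, 1, 0.015))]:
        res = simulate(proto, arr, params, T=proto.end_time + 0.5, cfg=cfg)
        rows.append({"protocol": name,
                     "dw_spine1": res.delta_w[0], "dw_spine2": res.delta_w[1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Input-timing plasticity windows
# ---------------------------------------------------------------------------

@dataclass
class TemporalWindowCurve:
    """Final weight change of both spines across an input-timing grid."""

    delta_t_ms: np.ndarray       # sorted grid, ms
    dw: np.ndarray               # (n_points, 2): spine 1 and spine 2
    distance: float              # um
    protocol_kind: str           # "paired" | "triplet"
    patterns: tuple[str, str] = ("", "")
    dw_isolated: np.ndarray | None = None   # (2,) each spine stimulated alone

    def __post_init__(self) -> None:
        self.delta_t_ms = np.asarray(self.delta_t_ms, dtype=float)
        self.dw = np.asarray(self.dw, dtype=float)
        if np.any(np.diff(self.delta_t_ms) <= 0):
            raise InvalidParameterError("delta_t grid must be strictly increasing")
        if not np.all(np.isfinite(self.dw)):
            raise InvalidParameterError("dw must be finite")

    def max_heterosynaptic(self) -> float:
        """Largest deviation of any spine's outcome from its isolated value.

        The isolated value is the weight change each spine shows when its own
        spike train is delivered with the partner silent; everything beyond
        that is mediated by calcium arriving through the shaft from the
        partner, so the maximum |dw - dw_isolated| over the grid measures the
        strength of the heterosynaptic interaction.
        """
        if self.dw_isolated is None:
            raise InvalidParameterError("curve lacks isolated reference values")
        return float(np.abs(self.dw - self.dw_isolated).max())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_t_ms": self.delta_t_ms,
            "dw_spine1": self.dw[:, 0], "dw_spine2": self.dw[:, 1]})


def classify_window(dw, epsilon: float = DEAD_BAND) -> str:
    """Compress a weight-change curve into its ordered P/D pattern string.

    Values within ``epsilon`` of zero are ignored; consecutive runs of the
    same sign collapse to one letter ("P" potentiation, "D" depression).
    An everywhere-flat curve gives "none".
    """
    if epsilon <= 0:
        raise InvalidParameterError("epsilon must be positive")
    dw = np.asarray(dw, dtype=float)
    letters = []
    for v in dw:
        if abs(v) < epsilon:
            continue
        letter = "P" if v > 0 else "D"
        if not letters or letters[-1] != letter:
            letters.append(letter)
    return "".join(letters) or "none"


def timing_sweep(delta_t_grid_ms, protocol_kind: str = "paired",
                 params: ModelParameters | None = None,
                 distance: float = 1.0,
                 weights: tuple[float, float] = (0.5, 0.5),
                 repetitions: int = 5,
                 inter_input: float = 0.02,
                 dt: float = 1e-4,
                 dx: float = 0.5,
                 length: float = 20.0,
                 epsilon: float = DEAD_BAND) -> TemporalWindowCurve:
    """Final delta w of both spines for every inter-input interval in the grid.

    ``delta_t_grid_ms`` spans at most [-100, 100] ms; positive values mean
    spine 2 is stimulated after spine 1.  Each grid point runs a fresh
    simulation from identical initial weights.
    """
    grid = np.asarray(sorted(delta_t_grid_ms), dtype=float)
    if grid.size == 0 or grid.min() < -100 - 1e-9 or grid.max() > 100 + 1e-9:
        raise InvalidParameterError("delta_t grid must lie within [-100, 100] ms")
    if protocol_kind not in ("paired", "triplet"):
        raise InvalidParameterError(f"unknown protocol kind {protocol_kind!r}")
    params = params or default_parameters("fig4-grid")
    arr = two_spine_arrangement(distance=distance, weights=weights,
                                dx=dx, length=length)
    cfg = SolverConfig(dt=dt, store_every=10 ** 9)
    dw = np.empty((grid.size, 2))
    for i, dt_ms in enumerate(grid):
        if protocol_kind == "paired":
            proto = paired_timing(0, 1, dt_ms / 1e3, repetitions=repetitions)
        else:
            proto = triplet(0, 1, dt_ms / 1e3, inter_input=inter_input,
                            repetitions=repetitions)
        res = simulate(proto, arr, params, T=proto.end_time + 0.5, cfg=cfg)
        dw[i] = res.delta_w

    # isolated references: each spine driven by its own train, partner silent
    from .stimulation import burst, single_spike

    if protocol_kind == "paired":
        solo_a = single_spike(0, repetitions=repetitions)
    else:
        solo_a = burst(0, n_spikes=2, isi=inter_input, repetitions=repetitions)
    solo_b = single_spike(1, repetitions=repetitions)
    dw_iso = np.array([
        simulate(solo_a, arr, params, T=solo_a.end_time + 0.5, cfg=cfg).delta_w[0],
        simulate(solo_b, arr, params, T=solo_b.end_time + 0.5, cfg=cfg).delta_w[1],
    ])
    curve = TemporalWindowCurve(delta_t_ms=grid, dw=dw, distance=distance,
                                protocol_kind=protocol_kind, dw_isolated=dw_iso)
    curve.patterns = (classify_window(dw[:, 0], epsilon),
                      classify_window(dw[:, 1], epsilon))
    return curve


# ---------------------------------------------------------------------------
# Multi-spine frequency regimes
# ---------------------------------------------------------------------------

@dataclass
class GroupOutcome:
    """Per-group mean/std of the group-mean delta w across configurations."""

    mean: dict
    std: dict
    n_configs: int
    per_config: pd.DataFrame = field(repr=False, default=None)

    def sign(self, group: str, dead_band: float = DEAD_BAND) -> int:
        mu = self.mean[group]
        return 0 if abs(mu) < dead_band else int(np.sign(mu))


def multi_spine_experiment(frequency_preset: str, D: float,
                           n_configs: int = 20, master_seed: int = 0,
                           params: ModelParameters | None = None,
                           arrangement_config: ArrangementConfig | None = None,
                           dt: float = 1e-4) -> GroupOutcome:
    """Frequency stimulation of the Stim group across random arrangements.

    For each configuration a fresh arrangement is generated, the named
    frequency protocol is applied synchronously to all Stim spines, and the
    final weight changes are aggregated by group.
    """
    if n_configs < 1:
        raise InvalidParameterError("n_configs must be >= 1")
    preset = FREQUENCY_PRESETS[frequency_preset]
    params = (params or default_parameters("fig3")).replace(D=D)
    cfg = SolverConfig(dt=dt, store_every=10 ** 9)
    rows = []
    for k in range(n_configs):
        arr = generate_arrangement(config_seed(master_seed, k),
                                   arrangement_config)
        proto = frequency_protocol(list(arr.group_indices("Stim")),
                                   preset["rate_hz"], int(preset["n_pulses"]))
        res = simulate(proto, arr, params, T=proto.end_time + 0.5, cfg=cfg)
        row = {"config": k, "seed": arr.seed}
        for g in GROUP_ORDER:
            row[g] = float(res.group_delta_w(g).mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    return GroupOutcome(
        mean={g: float(table[g].mean()) for g in GROUP_ORDER},
        std={g: float(table[g].std(ddof=0)) for g in GROUP_ORDER},
        n_configs=n_configs, per_config=table)


def matching_error(outcomes: dict[str, GroupOutcome],
                   expected_signs: dict[str, dict[str, int]] | None = None,
                   dead_band: float = DEAD_BAND) -> tuple[float, np.ndarray]:
    """Fraction of (configuration x frequency x group) sign mismatches.

    Each per-configuration group-mean delta w is mapped to a sign with the
    dead band and compared with the expected pattern.  Returns the overall
    error in [0, 1] together with the per-configuration errors.
    """
    expected_signs = expected_signs or EXPECTED_SIGN_PATTERNS
    freqs = sorted(outcomes)
    if set(freqs) != set(expected_signs) & set(freqs) or not freqs:
        raise InvalidParameterError("outcomes and expected_signs must cover "
                                    "the same frequencies")
    n_configs = {outcomes[f].n_configs for f in freqs}
    if len(n_configs) != 1:
        raise InvalidParameterError("all outcomes must share n_configs")
    n = n_configs.pop()
    mismatch = np.zeros(n)
    cells = 0
    for f in freqs:
        table = outcomes[f].per_config
        if set(GROUP_ORDER) - set(table.columns):
            raise InvalidParameterError("outcome table missing group columns")
        for g in GROUP_ORDER:
            vals = table[g].to_numpy()
            signs = np.where(np.abs(vals) < dead_band, 0, np.sign(vals))
            mismatch += signs != expected_signs[f][g]
            cells += 1
    per_config = mismatch / cells
    return float(per_config.mean()), per_config


def diffusion_sweep(D_list, frequency_presets=("low", "medium", "high"),
                    n_configs: int = 20, master_seed: int = 0,
                    params: ModelParameters | None = None,
                    dt: float = 1e-4) -> pd.DataFrame:
    """Matching error per diffusion constant, aggregated over frequencies,
    groups and configurations."""
    if len(list(D_list)) == 0:
        raise InvalidParameterError("D_list must be non-empty")
    rows = []
    for D in D_list:
        outcomes = {f: multi_spine_experiment(f, D, n_configs, master_seed,
                                              params=params, dt=dt)
                    for f in frequency_presets}
        err, per_config = matching_error(outcomes)
        row = {"D": D, "error_mean": err,
               "error_std": float(per_config.std(ddof=0))}
        for f in frequency_presets:
            for g in GROUP_ORDER:
                row[f"{f}_{g}_mean"] = outcomes[f].mean[g]
                row[f"{f}_{g}_std"] = outcomes[f].std[g]
        rows.append(row)
    return pd.DataFrame(rows)
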