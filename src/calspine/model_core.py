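"""Physical parameters, cable geometry and spine arrangements.

The dendrite is a cylinder of radius ``r_d`` discretized into segments of
length ``dx``; spines are spheres of radius ``r_s`` attached to individual
segments through a neck of length ``l_n`` and radius ``a_s``.  Spine and
dendrite exchange calcium at first-order rates given by inverse mean first
passage times through the neck:

    k_d = 4 D a_s / V_d                  (dendrite -> spine)
    k_s = 1 / (V_s / (4 D a_s) + l_n^2 / (2 D))   (spine -> dendrite)

with V_d = pi r_d^2 dx and V_s = (4/3) pi r_s^3.

Internal units are s, um and uM throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .presets import PLASTICITY_PRESETS

#: Faraday constant (C/mol).
FARADAY = 96485.0

#: Spine group labels used by the arrangement generator.
GROUPS = ("Stim", "Un_in", "Un_out", "plain")


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain constraint."""


class GenerationError(RuntimeError):
    """The arrangement generator could not satisfy its constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """All physical constants and calcium/plasticity parameters of one run.

    Defaults are the physiological values used throughout: free-calcium
    diffusion constant 220 um^2/s, leak time constant 80 ms, standard spine
    morphology, and a representative synaptic calcium influx (fraction
    ``gamma`` of an exponentially decaying electrical current).  Plasticity
    thresholds/rates default to the ``fig2`` preset.
    """

    D: float = 220.0          # free Ca2+ diffusion constant, um^2/s
    tau_decay: float = 0.08   # calcium leak time constant, s
    l_n: float = 0.5          # spine neck length, um
    a_s: float = 0.1          # spine neck radius, um
    r_s: float = 0.34         # spine head radius, um
    r_d: float = 1.0          # dendrite radius, um
    gamma: float = 0.11       # fraction of current carried by Ca2+
    z: float = 2.0            # calcium valence
    F: float = FARADAY        # Faraday constant, C/mol
    I0: float = 0.1           # synaptic current amplitude, pA
    tau_d: float = 1e-3       # synaptic current decay, s
    theta_p: float = 4e-3     # potentiation threshold, uM
    theta_d: float = 2e-3     # depression threshold, uM
    gamma_p: float = 16.0     # potentiation rate, 1/s (calibrated)
    gamma_d: float = 8.25     # depression rate, 1/s (calibrated)

    def __post_init__(self) -> None:
        for name in ("tau_decay", "l_n", "a_s", "r_s", "r_d", "z", "F",
                     "I0", "tau_d", "gamma_p", "gamma_d"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.D < 0:
            raise InvalidParameterError("D must be non-negative")
        if not 0 < self.gamma <= 1:
            raise InvalidParameterError("gamma must lie in (0, 1]")
        if not 0 < self.theta_d < self.theta_p:
            raise InvalidParameterError("thresholds must satisfy 0 < theta_d < theta_p")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def with_preset(self, preset: str | dict) -> "ModelParameters":
        """Return a copy with thresholds/rates taken from a named preset."""
        values = PLASTICITY_PRESETS[preset] if isinstance(preset, str) else preset
        return self.replace(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_parameters(preset: str = "fig2") -> ModelParameters:
    """Physiological defaults with thresholds/rates from a named preset."""
    return ModelParameters().with_preset(preset)


@dataclass(frozen=True)
class Geometry:
    """Discretized unbranched cable: ``n_segments`` segments of length ``dx``."""

    length: float            # um
    dx: float                # segment length l_d, um
    n_segments: int
    boundary: str = "no-flux"

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.length <= 0:
            raise InvalidParameterError("length and dx must be positive")
        if self.n_segments < 2:
            raise InvalidParameterError("need at least 2 segments")
        if abs(self.n_segments * self.dx - self.length) > 1e-9 * self.length:
            raise InvalidParameterError("n_segments * dx must equal length")
        if self.boundary != "no-flux":
            raise InvalidParameterError(f"unknown boundary condition {self.boundary!r}")

    @classmethod
    def from_length(cls, length: float, dx: float = 0.5,
                    boundary: str = "no-flux") -> "Geometry":
        n = int(round(length / dx))
        return cls(length=n * dx, dx=dx, n_segments=n, boundary=boundary)

    @property
    def centers(self) -> np.ndarray:
        """Segment-center positions in um."""
        return (np.arange(self.n_segments) + 0.5) * self.dx


def compartment_volumes(params: ModelParameters, dx: float) -> tuple[float, float]:
    """Volumes (um^3) of one dendritic segment and of the spine head."""
    if dx <= 0:
        raise InvalidParameterError("dx must be positive")
    V_d = math.pi * params.r_d ** 2 * dx
    V_s = (4.0 / 3.0) * math.pi * params.r_s ** 3
    return V_d, V_s


def coupling_rates(params: ModelParameters, dx: float) -> tuple[float, float]:
    """Spine-dendrite exchange rates (k_d, k_s) in 1/s.

    Both are inverse mean first passage times through the spine neck.  For
    D = 0 no exchange is possible; both rates are returned as 0 with a
    warning rather than dividing by zero.
    """
    V_d, V_s = compartment_volumes(params, dx)
    if params.D == 0:
        warnings.warn("D = 0: spine-dendrite exchange rates set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0, 0.0
    k_d = 4.0 * params.D * params.a_s / V_d
    tau_prime = V_s / (4.0 * params.D * params.a_s) + params.l_n ** 2 / (2.0 * params.D)
    return k_d, 1.0 / tau_prime


@dataclass(frozen=True)
class SpineArrangement:
    """Spine positions, group labels and initial weights on a cable.

    Spines sit at segment centers, at most one per segment.  ``cluster_window``
    records the (start, length) in um of the stimulated-cluster section when
    the arrangement was produced by the generator.
    """

    geometry: Geometry
    spine_segments: tuple[int, ...]
    groups: tuple[str, ...]
    initial_weights: tuple[float, ...]
    seed: int | None = None
    cluster_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        n = len(self.spine_segments)
        if len(self.groups) != n or len(self.initial_weights) != n:
            raise InvalidParameterError("groups/weights must match spine count")
        if len(set(self.spine_segments)) != n:
            raise InvalidParameterError("at most one spine per segment")
        for s in self.spine_segments:
            if not 0 <= s < self.geometry.n_segments:
                raise InvalidParameterError(f"spine segment {s} outside geometry")
        for g in self.groups:
            if g not in GROUPS:
                raise InvalidParameterError(f"unknown group label {g!r}")
        for w in self.initial_weights:
            if not 0.0 <= w <= 1.0:
                raise InvalidParameterError("initial weights must lie in [0, 1]")

    @property
    def n_spines(self) -> int:
        return len(self.spine_segments)

    @property
    def positions(self) -> np.ndarray:
        """Spine positions (segment centers) in um."""
        return self.geometry.centers[np.asarray(self.spine_segments, dtype=int)]

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group], dtype=int)

    def mirrored(self) -> "SpineArrangement":
        """Reflection about the cable midpoint (spine order preserved)."""
        n = self.geometry.n_segments
        return dataclasses.replace(
            self,
            spine_segments=tuple(n - 1 - s for s in self.spine_segments),
            cluster_window=None if self.cluster_window is None else (
                self.geometry.length - self.cluster_window[0] - self.cluster_window[1],
                self.cluster_window[1],
            ),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "length_um": self.geometry.length,
            "dx_um": self.geometry.dx,
            "boundary": self.geometry.boundary,
            "positions_um": list(map(float, self.positions)),
            "groups": list(self.groups),
            "initial_weights": list(map(float, self.initial_weights)),
            "seed": self.seed,
            "cluster_window_um": self.cluster_window,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SpineArrangement":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        geom = Geometry.from_length(d["length_um"], d["dx_um"],
                                    d.get("boundary", "no-flux"))
        segments = tuple(int(round(p / geom.dx - 0.5)) for p in d["positions_um"])
        window = d.get("cluster_window_um")
        return cls(
            geometry=geom,
            spine_segments=segments,
            groups=tuple(d["groups"]),
            initial_weights=tuple(d["initial_weights"]),
            seed=d.get("seed"),
            cluster_window=None if window is None else tuple(window),
        )


@dataclass(frozen=True)
class ArrangementConfig:
    """Constraints for the random arrangement generator.

    Defaults emulate the multi-spine study conditions: an 80 um dendrite with
    16 spines of which 10 (7 stimulated + 3 unstimulated) are confined to a
    7 um cluster section (density ~1.4 spines/um), and at least 3 unstimulated
    spines on each flank outside the cluster.
    """

    length: float = 80.0
    dx: float = 0.5
    n_spines: int = 16
    n_stim: int = 7
    n_un_in: int = 3
    window_length: float = 7.0
    min_outer_per_side: int = 3
    weight_low: float = 0.3
    weight_high: float = 0.7
    stim_contiguous: bool = False
    max_retries: int = 100

    @property
    def n_outer(self) -> int:
        return self.n_spines - self.n_stim - self.n_un_in


def generate_arrangement(seed: int,
                         config: ArrangementConfig | None = None) -> SpineArrangement:
    """Draw a random spine arrangement satisfying the cluster constraints.

    The cluster window is placed uniformly at random subject to leaving at
    least ``min_outer_per_side`` segments on each flank; the in-window spines
    occupy distinct random segments of the window and the outer spines are
    split evenly between the two flanks.  Deterministic given ``seed``.
    """
    cfg = config or ArrangementConfig()
    geom = Geometry.from_length(cfg.length, cfg.dx)
    rng = np.random.default_rng(seed)

    n_window = int(round(cfg.window_length / cfg.dx))
    n_in_window = cfg.n_stim + cfg.n_un_in
    n_side = cfg.min_outer_per_side
    if cfg.n_outer < 2 * n_side:
        raise GenerationError(
            f"constraint violated: {cfg.n_outer} outer spines cannot provide "
            f"{n_side} per flank")
    if n_in_window > n_window:
        raise GenerationError(
            "constraint violated: cluster window too short for "
            f"{n_in_window} spines at dx={cfg.dx}")

    n_left_extra = cfg.n_outer - 2 * n_side
    for _ in range(cfg.max_retries):
        lo, hi = n_side, geom.n_segments - n_window - n_side
        if hi < lo:
            raise GenerationError("constraint violated: dendrite too short for "
                                  "the cluster window plus flank spines")
        start = int(rng.integers(lo, hi + 1))
        window_segments = np.arange(start, start + n_window)

        if cfg.stim_contiguous:
            # Stim spines occupy a contiguous random run inside the window.
            offs = np.sort(rng.choice(n_window, size=n_in_window, replace=False))
            stim_first = int(rng.integers(0, cfg.n_un_in + 1))
            labels_in = np.array(["Un_in"] * n_in_window, dtype=object)
            labels_in[stim_first:stim_first + cfg.n_stim] = "Stim"
            in_segs = window_segments[offs]
        else:
            offs = rng.choice(n_window, size=n_in_window, replace=False)
            in_segs = np.sort(window_segments[offs])
            labels_in = np.array(["Stim"] * cfg.n_stim + ["Un_in"] * cfg.n_un_in,
                                 dtype=object)
            rng.shuffle(labels_in)

        left_pool = np.arange(0, start)
        right_pool = np.arange(start + n_window, geom.n_segments)
        n_left = n_side + int(rng.integers(0, n_left_extra + 1))
        n_right = cfg.n_outer - n_left
        if len(left_pool) < n_left or len(right_pool) < n_right:
            continue
        left = np.sort(rng.choice(left_pool, size=n_left, replace=False))
        right = np.sort(rng.choice(right_pool, size=n_right, replace=False))

        segments = np.concatenate([left, in_segs, right])
        labels = np.concatenate([np.array(["Un_out"] * n_left, dtype=object),
                                 labels_in,
                                 np.array(["Un_out"] * n_right, dtype=object)])
        order = np.argsort(segments)
        segments, labels = segments[order], labels[order]
        weights = rng.uniform(cfg.weight_low, cfg.weight_high, size=cfg.n_spines)
        return SpineArrangement(
            geometry=geom,
            spine_segments=tuple(int(s) for s in segments),
            groups=tuple(labels),
            initial_weights=tuple(float(w) for w in weights),
            seed=seed,
            cluster_window=(start * cfg.dx, n_window * cfg.dx),
        )
    raise GenerationError("constraint violated: flank spine placement failed "
                          f"after {cfg.max_retries} retries")


def two_spine_arrangement(distance: float = 1.0,
                          length: float = 20.0,
                          dx: float = 0.5,
                          weights: tuple[float, float] = (0.5, 0.5),
                          groups: tuple[str, str] = ("plain", "plain"),
                          ) -> SpineArrangement:
    """Two spines ``distance`` um apart near the middle of a short cable."""
    geom = Geometry.from_length(length, dx)
    gap = int(round(distance / dx))
    if abs(gap * dx - distance) > 1e-9:
        raise InvalidParameterError("distance must be a multiple of dx")
    if gap < 1:
        raise InvalidParameterError("spines must occupy distinct segments")
    i_a = geom.n_segments // 2 - (gap + 1) // 2
    return SpineArrangement(
        geometry=geom,
        spine_segments=(i_a, i_a + gap),
        groups=groups,
        initial_weights=weights,
    )


def bare_cable(length: float, dx: float = 0.5) -> SpineArrangement:
    """A cable with no spines (useful for pure-diffusion analyses)."""
    return SpineArrangement(
        geometry=Geometry.from_length(length, dx),
        spine_segments=(), groups=(), initial_weights=(),
    )
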