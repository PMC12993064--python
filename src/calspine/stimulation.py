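"""Stimulation protocols: per-spine presynaptic spike-time lists.

Each named builder produces one repetition's spike pattern and expands it
over ``repetitions`` presentations spaced ``repetition_interval`` apart
(default 5 presentations, 1 s apart -- long against the 80 ms calcium leak,
so calcium effectively resets between presentations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .presets import FREQUENCY_PRESETS

#: Lead-in before the first spike of a presentation (s).
T_LEAD = 0.01


class ProtocolError(ValueError):
    """Invalid protocol construction arguments."""


@dataclass(frozen=True)
class StimulationProtocol:
    """Explicit per-spine spike times in seconds.

    ``spikes`` maps spine index -> sorted tuple of spike times; spines without
    an entry are silent.  Times are already expanded over repetitions.
    """

    spikes: dict[int, tuple[float, ...]]
    repetitions: int = 1
    repetition_interval: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        for spine, times in self.spikes.items():
            arr = np.asarray(times)
            if arr.size and (np.any(arr < 0) or np.any(np.diff(arr) < 0)):
                raise ProtocolError(
                    f"spike times for spine {spine} must be sorted and >= 0")

    def times_for(self, spine: int) -> np.ndarray:
        return np.asarray(self.spikes.get(spine, ()), dtype=float)

    @property
    def end_time(self) -> float:
        """Time of the last spike (0.0 for an empty protocol)."""
        return max((t[-1] for t in self.spikes.values() if t), default=0.0)

    def n_spikes(self, spine: int | None = None) -> int:
        if spine is not None:
            return len(self.spikes.get(spine, ()))
        return sum(len(t) for t in self.spikes.values())

    def shifted(self, offset: float) -> "StimulationProtocol":
        return replace(self, spikes={
            s: tuple(t + offset for t in ts) for s, ts in self.spikes.items()})

    def relabeled(self, mapping: dict[int, int]) -> "StimulationProtocol":
        """Remap spine indices (e.g. to mirror an arrangement)."""
        return replace(self, spikes={mapping[s]: ts for s, ts in self.spikes.items()})

    # -- serialization (times stored in ms) ---------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "label": self.label,
            "repetitions": self.repetitions,
            "repetition_interval_ms": self.repetition_interval * 1e3,
            "spikes_ms": {str(s): [t * 1e3 for t in ts]
                          for s, ts in sorted(self.spikes.items())},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StimulationProtocol":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            spikes={int(s): tuple(t / 1e3 for t in ts)
                    for s, ts in d["spikes_ms"].items()},
            repetitions=d.get("repetitions", 1),
            repetition_interval=d.get("repetition_interval_ms", 1e3) / 1e3,
            label=d.get("label", ""),
        )


def _expand(base: dict[int, list[float]], repetitions: int,
            interval: float, label: str) -> StimulationProtocol:
    if repetitions < 1:
        raise ProtocolError("repetitions must be >= 1")
    spikes = {
        spine: tuple(sorted(t + k * interval
                            for k in range(repetitions) for t in times))
        for spine, times in base.items()
    }
    return StimulationProtocol(spikes=spikes, repetitions=repetitions,
                               repetition_interval=interval, label=label)


def single_spike(spine: int, repetitions: int = 5,
                 repetition_interval: float = 1.0) -> StimulationProtocol:
    """One spike per presentation at one spine; all other spines silent."""
    if spine < 0:
        raise ProtocolError("unknown spine id")
    return _expand({spine: [T_LEAD]}, repetitions, repetition_interval,
                   "single_spike")


def burst(spine: int, n_spikes: int = 5, isi: float = 0.025,
          repetitions: int = 5,
          repetition_interval: float = 1.0) -> StimulationProtocol:
    """``n_spikes`` equally spaced spikes per presentation at one spine."""
    if spine < 0:
        raise ProtocolError("unknown spine id")
    if n_spikes < 1 or (n_spikes > 1 and isi <= 0):
        raise ProtocolError("need n_spikes >= 1 and isi > 0")
    times = [T_LEAD + i * isi for i in range(n_spikes)]
    return _expand({spine: times}, repetitions, repetition_interval, "burst")


def paired_timing(spine_a: int, spine_b: int, delta_t: float,
                  repetitions: int = 5,
                  repetition_interval: float = 1.0) -> StimulationProtocol:
    """Per presentation: spine_a fires at t0, spine_b at t0 + delta_t.

    Negative delta_t makes spine_b fire first; t0 shifts so all times stay
    non-negative.
    """
    if spine_a == spine_b:
        raise ProtocolError("paired_timing requires two distinct spines")
    t0 = T_LEAD + max(0.0, -delta_t)
    return _expand({spine_a: [t0], spine_b: [t0 + delta_t]},
                   repetitions, repetition_interval, "paired_timing")


def triplet(spine_a: int, spine_b: int, delta_t: float,
            inter_input: float = 0.02, repetitions: int = 5,
            repetition_interval: float = 1.0) -> StimulationProtocol:
    """Two spikes at spine_a (``inter_input`` apart) and one at spine_b.

    ``delta_t`` is referenced to the first spike at spine_a.
    """
    if spine_a == spine_b:
        raise ProtocolError("triplet requires two distinct spines")
    if inter_input <= 0:
        raise ProtocolError("inter_input must be positive")
    t0 = T_LEAD + max(0.0, -delta_t)
    return _expand({spine_a: [t0, t0 + inter_input], spine_b: [t0 + delta_t]},
                   repetitions, repetition_interval, "triplet")


def frequency_protocol(spines, rate: float, n_pulses: int = 5) -> StimulationProtocol:
    """Synchronous spike trains at ``rate`` Hz on every listed spine."""
    spines = list(spines)
    if not spines:
        raise ProtocolError("need at least one spine")
    if rate <= 0 or n_pulses < 1:
        raise ProtocolError("rate must be > 0 and n_pulses >= 1")
    times = [T_LEAD + i / rate for i in range(n_pulses)]
    return _expand({s: list(times) for s in spines}, 1, 1.0,
                   f"frequency_{rate:g}Hz")


def frequency_preset(spines, name: str) -> StimulationProtocol:
    """Named low/medium/high frequency protocol (calibrated stand-ins)."""
    p = FREQUENCY_PRESETS[name]
    proto = frequency_protocol(spines, p["rate_hz"], int(p["n_pulses"]))
    return replace(proto, label=f"frequency_{name}")
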