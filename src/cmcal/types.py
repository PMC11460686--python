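"""Core value types shared across the calibration pipeline.

The calibration currency is the :class:`Trace` — a uniformly sampled pair of
membrane-potential and intracellular-calcium series — and the parameter
currency is the :class:`ConductanceSet` — 16 dimensionless multipliers on the
maximal conductances / fluxes of the baseline iPSC-CM model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Canonical ordering of the 16 scaled maximal-conductance parameters.
CONDUCTANCE_NAMES: tuple[str, ...] = (
    "g_Na", "g_f", "g_CaL", "g_CaT", "g_to", "g_Kr", "g_Ks", "g_K1",
    "g_NaK", "g_NaCa", "g_PCa", "g_bNa", "g_bCa", "g_up", "g_SRleak", "g_rel",
)

#: Registry of current / flux names accepted by a BlockMap, index-aligned
#: with CONDUCTANCE_NAMES (blocking ``I_Kr`` scales ``g_Kr`` and so on).
CURRENT_NAMES: tuple[str, ...] = (
    "I_Na", "I_f", "I_CaL", "I_CaT", "I_to", "I_Kr", "I_Ks", "I_K1",
    "I_NaK", "I_NaCa", "I_PCa", "I_bNa", "I_bCa", "J_up", "J_leak", "J_rel",
)

CURRENT_TO_CONDUCTANCE: dict[str, str] = dict(zip(CURRENT_NAMES, CONDUCTANCE_NAMES))


@dataclass(frozen=True)
class ConductanceSet:
    """16 strictly positive multipliers on the baseline model conductances.

    The all-ones set reproduces the baseline model exactly.
    """

    values: tuple[float, ...] = (1.0,) * 16

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) != len(CONDUCTANCE_NAMES):
            raise ValueError(f"expected {len(CONDUCTANCE_NAMES)} multipliers, got {len(vals)}")
        if not all(np.isfinite(vals)):
            raise ValueError("multipliers must be finite")
        if any(v < 0 for v in vals):
            raise ValueError("multipliers must be non-negative")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_dict(cls, d: Mapping[str, float], default: float = 1.0) -> "ConductanceSet":
        unknown = set(d) - set(CONDUCTANCE_NAMES)
        if unknown:
            raise KeyError(f"unknown conductance names: {sorted(unknown)}")
        return cls(tuple(float(d.get(name, default)) for name in CONDUCTANCE_NAMES))

    def to_dict(self) -> dict[str, float]:
        return dict(zip(CONDUCTANCE_NAMES, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[CONDUCTANCE_NAMES.index(name)]

    def with_(self, **kwargs: float) -> "ConductanceSet":
        d = self.to_dict()
        d.update(kwargs)
        return ConductanceSet.from_dict(d)


@dataclass(frozen=True)
class ExtracellularMilieu:
    """Bulk extracellular ion concentrations (mM). Defaults: Tyrode-like."""

    Na_o: float = 151.0
    Ca_o: float = 1.8
    K_o: float = 5.4

    def __post_init__(self) -> None:
        for name in ("Na_o", "Ca_o", "K_o"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


class BlockMap(dict):
    """Mapping current-name -> blocked fraction in [0, 1].

    Unlisted currents are unblocked; the effective multiplier of a blocked
    current is ``base_multiplier * (1 - fraction)``.
    """

    def __init__(self, blocks: Mapping[str, float] | None = None, **kwargs: float):
        merged = dict(blocks or {})
        merged.update(kwargs)
        for name, frac in merged.items():
            if name not in CURRENT_TO_CONDUCTANCE:
                raise KeyError(
                    f"unknown current {name!r}; known currents: {', '.join(CURRENT_NAMES)}"
                )
            if not 0.0 <= float(frac) <= 1.0:
                raise ValueError(f"block fraction for {name} must be in [0, 1], got {frac}")
        super().__init__({k: float(v) for k, v in merged.items()})


def apply_block(c: ConductanceSet, blocks: BlockMap | Mapping[str, float]) -> ConductanceSet:
    """Scale the targeted multipliers by (1 - blocked fraction).

    >>> apply_block(ConductanceSet(), BlockMap({"I_Kr": 0.30}))["g_Kr"]
    0.7
    """
    blocks = blocks if isinstance(blocks, BlockMap) else BlockMap(blocks)
    d = c.to_dict()
    for current, frac in blocks.items():
        g = CURRENT_TO_CONDUCTANCE[current]
        d[g] = d[g] * (1.0 - frac)
    return ConductanceSet.from_dict(d)


@dataclass(frozen=True)
class StimulusSpec:
    """Periodic square-pulse stimulus current (inward), density in pA/pF.

    The first pulse begins at t = period on the condition clock.
    """

    amplitude: float = 60.0
    width_ms: float = 1.0
    period_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.period_ms <= self.width_ms:
            raise ValueError("stimulus period must exceed pulse width")
        if self.amplitude <= 0 or self.width_ms <= 0:
            raise ValueError("stimulus amplitude and width must be positive")

    @classmethod
    def paced(cls, hz: float, amplitude: float = 60.0, width_ms: float = 1.0) -> "StimulusSpec":
        return cls(amplitude=amplitude, width_ms=width_ms, period_ms=1000.0 / hz)


@dataclass
class Trace:
    """Uniformly sampled V(t) / Cai(t) segment.

    ``V`` is in mV and ``Ca`` in mM unless ``normalized`` is set, in which
    case both span [0, 1].  ``failed`` marks an aborted integration; failed
    traces are sentinels for downstream fitness, never exceptions.
    """

    t: np.ndarray
    V: np.ndarray
    Ca: np.ndarray
    normalized: bool = False
    failed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.Ca = np.asarray(self.Ca, dtype=float)
        if not (len(self.t) == len(self.V) == len(self.Ca)):
            raise ValueError("time, V and Ca series must have equal length")
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValueError("trace has fewer than 2 samples")
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def copy(self) -> "Trace":
        return Trace(self.t.copy(), self.V.copy(), self.Ca.copy(),
                     normalized=self.normalized, failed=self.failed,
                     meta=dict(self.meta))


__all__ = [
    "CONDUCTANCE_NAMES", "CURRENT_NAMES", "CURRENT_TO_CONDUCTANCE",
    "ConductanceSet", "ExtracellularMilieu", "BlockMap", "apply_block",
    "StimulusSpec", "Trace",
]
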