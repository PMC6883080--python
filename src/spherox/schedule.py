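"""Piecewise-constant oxygen schedules for cycling-hypoxia experiments.

An :class:`OxygenSchedule` describes the gas-phase oxygen level supplied to a
microfluidic culture channel as an ordered list of (duration, %O2) phases that
repeats ``repeat_count`` times, e.g. the cycling-hypoxia profile
``2 h 0% O2, 6 h 3% O2, 4 h 10% O2``.  Phases are left-closed, right-open in
time, so a lookup at any instant inside the schedule returns exactly one
oxygen level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

O2_MAX_PCT = 25.0


@dataclass(frozen=True)
class Phase:
    """One constant-oxygen gas phase."""

    duration_min: float
    o2_pct: float

    def __post_init__(self) -> None:
        if not self.duration_min > 0:
            raise ValueError(f"phase duration must be > 0 min, got {self.duration_min}")
        if not 0.0 <= self.o2_pct <= O2_MAX_PCT:
            raise ValueError(
                f"o2 must be in [0, {O2_MAX_PCT}] % of 1 atm, got {self.o2_pct}"
            )


@dataclass(frozen=True)
class OxygenSchedule:
    """Repeating sequence of constant-oxygen phases.

    Parameters
    ----------
    phases:
        Ordered gas phases of one cycle, as :class:`Phase` objects or
        ``(duration_min, o2_pct)`` tuples.
    repeat_count:
        Number of times the cycle repeats (>= 1).
    """

    phases: tuple[Phase, ...]
    repeat_count: int = 1

    def __init__(self, phases: Sequence, repeat_count: int = 1):
        parsed = tuple(p if isinstance(p, Phase) else Phase(*p) for p in phases)
        if not parsed:
            raise ValueError("schedule needs at least one phase")
        if not (isinstance(repeat_count, (int,)) and repeat_count >= 1):
            raise ValueError(f"repeat_count must be an integer >= 1, got {repeat_count}")
        object.__setattr__(self, "phases", parsed)
        object.__setattr__(self, "repeat_count", int(repeat_count))

    @property
    def cycle_min(self) -> float:
        """Duration of one cycle in minutes."""
        return float(sum(p.duration_min for p in self.phases))

    @property
    def total_min(self) -> float:
        """Total schedule duration in minutes."""
        return self.cycle_min * self.repeat_count

    def o2_at(self, t_min: float) -> float:
        """Oxygen level (% of 1 atm) at time ``t_min`` in [0, total_min).

        Phases are left-closed, right-open; times at or beyond the end of the
        schedule raise ``ValueError``.
        """
        if t_min < 0 or t_min >= self.total_min:
            raise ValueError(
                f"t={t_min} min outside schedule [0, {self.total_min}) min"
            )
        t = t_min % self.cycle_min
        for p in self.phases:
            if t < p.duration_min:
                return p.o2_pct
            t -= p.duration_min
        # numerically t == cycle_min only through float round-off; last phase
        return self.phases[-1].o2_pct

    def intervals(self) -> Iterator[tuple[float, float, float]]:
        """Yield ``(t_start, t_end, o2_pct)`` over every phase of every repeat."""
        t = 0.0
        for _ in range(self.repeat_count):
            for p in self.phases:
                yield t, t + p.duration_min, p.o2_pct
                t += p.duration_min

    def windows_at_level(self, o2_pct: float, atol: float = 1e-9) -> list[tuple[float, float]]:
        """Time windows ``[t_start, t_end)`` where the schedule sits at ``o2_pct``."""
        return [
            (a, b) for a, b, o2 in self.intervals() if abs(o2 - o2_pct) <= atol
        ]

    def o2_levels(self) -> tuple[float, ...]:
        """Distinct oxygen levels used, in first-appearance order."""
        seen: list[float] = []
        for p in self.phases:
            if p.o2_pct not in seen:
                seen.append(p.o2_pct)
        return tuple(seen)
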