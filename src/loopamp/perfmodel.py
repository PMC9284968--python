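"""Sequencer performance model: time to a support threshold, and the
amplification amount minimizing total end-to-end time.

The model is a transparent rate product: useful calls arrive at

    rate(t) = active_pores * participation(t) * per_pore_read_rate
              * (1 - barcode_loss) * target_fraction * call_yield

where participation optionally ramps linearly from ``ramp_initial`` to
the steady value over ``ramp_duration`` seconds (low pore participation
is common early in a run).  Sequencing time is the t at which the
integrated rate reaches the required support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_SUPPORT = 250

__all__ = [
    "SequencerModel",
    "AmplificationCurve",
    "OptimalAmplification",
    "NoFeasibleAmplificationError",
    "sequencing_time",
    "optimal_amplification",
]


class NoFeasibleAmplificationError(ValueError):
    """Every sweep point has zero target fraction."""


@dataclass(frozen=True)
class SequencerModel:
    active_pores: float
    per_pore_read_rate: float  # reads / second / pore
    participation: float = 1.0  # steady-state fraction of pores sequencing
    call_yield: float = 1.0  # P(target-class read yields a countable call)
    barcode_loss: float = 0.0
    ramp_initial: float | None = None  # None disables the startup ramp
    ramp_duration: float = 120.0  # seconds

    def __post_init__(self):
        if self.active_pores <= 0 or self.per_pore_read_rate <= 0:
            raise ValueError("pore count and read rate must be positive")
        for name in ("participation", "call_yield", "barcode_loss"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ramp_initial is not None and not 0 <= self.ramp_initial <= 1:
            raise ValueError("ramp_initial must lie in [0, 1]")
        if self.ramp_duration < 0:
            raise ValueError("ramp_duration must be >= 0")


@dataclass(frozen=True)
class AmplificationCurve:
    """Characterization sweep: (amount, target_fraction[, dna_mass])."""

    amounts: tuple[float, ...]
    fractions: tuple[float, ...]
    masses: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.amounts) != len(self.fractions) or not self.amounts:
            raise ValueError("curve needs equal-length, non-empty columns")
        if any(b <= a for a, b in zip(self.amounts, self.amounts[1:])):
            raise ValueError("amplification amounts must strictly increase")
        if any(not 0 <= f <= 1 for f in self.fractions):
            raise ValueError("target fractions must lie in [0, 1]")

    def fraction_at(self, amount: float) -> float:
        """Linear interpolation between sweep points (clamped at ends)."""
        return float(np.interp(amount, self.amounts, self.fractions))

    @classmethod
    def from_tsv(cls, path) -> "AmplificationCurve":
        amounts, fractions, masses = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                amounts.append(float(parts[0]))
                fractions.append(float(parts[1]))
                if len(parts) > 2:
                    masses.append(float(parts[2]))
        return cls(
            amounts=tuple(amounts),
            fractions=tuple(fractions),
            masses=tuple(masses) if len(masses) == len(amounts) else None,
        )


def sequencing_time(
    model: SequencerModel,
    target_fraction: float,
    support: int = DEFAULT_SUPPORT,
) -> float:
    """Seconds of sequencing needed to accumulate ``support`` calls.

    Returns math.inf when the target fraction is zero.
    """
    if target_fraction < 0 or target_fraction > 1:
        raise ValueError("target_fraction must lie in [0, 1]")
    if support < 1:
        raise ValueError("support must be >= 1")
    if target_fraction == 0:
        return math.inf
    base = (
        model.active_pores
        * model.per_pore_read_rate
        * (1 - model.barcode_loss)
        * target_fraction
        * model.call_yield
    )
    steady = model.participation
    r0 = model.ramp_initial
    if r0 is None or model.ramp_duration == 0 or r0 == steady:
        return support / (base * steady)
    T = model.ramp_duration
    # calls accumulated by the end of the ramp (trapezoid)
    ramp_total = base * T * (r0 + steady) / 2
    if support <= ramp_total:
        # solve base * (r0*t + (steady-r0) * t^2 / (2T)) == support
        a = base * (steady - r0) / (2 * T)
        b = base * r0
        disc = b * b + 4 * a * support
        return (-b + math.sqrt(disc)) / (2 * a)
    return T + (support - ramp_total) / (base * steady)


@dataclass(frozen=True)
class OptimalAmplification:
    amount: float
    total_time: float
    amp_time: float
    seq_time: float
    table: tuple[tuple[float, float, float, float, float], ...]
    # rows: (amount, fraction, amp_time, seq_time, total_time)


def optimal_amplification(
    curve: AmplificationCurve,
    model: SequencerModel,
    per_unit_amp_time: float = 1.0,
    fixed_overhead: float = 0.0,
    support: int = DEFAULT_SUPPORT,
    grid_points: int = 2001,
) -> OptimalAmplification:
    """Amplification amount minimizing amp + overhead + sequencing time.

    The curve is linearly interpolated and scanned on a dense grid that
    includes every sweep knot; the full total-time table is returned
    alongside the argmin.  ``per_unit_amp_time`` converts amounts to
    seconds (1.0 when amounts already are seconds).
    """
    if all(f == 0 for f in curve.fractions):
        raise NoFeasibleAmplificationError("target fraction is zero everywhere")
    lo, hi = curve.amounts[0], curve.amounts[-1]
    grid = np.unique(
        np.concatenate([np.linspace(lo, hi, grid_points), np.array(curve.amounts)])
    )
    best = None
    table = []
    for a in grid:
        f = curve.fraction_at(float(a))
        amp_t = float(a) * per_unit_amp_time
        seq_t = sequencing_time(model, f, support)
        total = amp_t + fixed_overhead + seq_t
        table.append((float(a), f, amp_t, seq_t, total))
        if best is None or total < best[1]:
            best = (float(a), total, amp_t, seq_t)
    amount, total, amp_t, seq_t = best
    return OptimalAmplification(
        amount=amount,
        total_time=total,
        amp_time=amp_t,
        seq_time=seq_t,
        table=tuple(table),
    )
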