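"""Field-trial spray accounting.

Three rates summarize a target-spraying pass over a trial strip:

* effective recognition rate ``u`` — weeds the detector identified at least
  once, divided by all weeds present;
* relative hit rate ``w'`` — weeds actually wetted by spray, divided by the
  identified ones;
* absolute hit rate ``w = u * w'`` — wetted weeds over all weeds.

The product identity holds exactly on the unrounded ratios since both sides
equal ``n_hit / n_total``; reported percentages are printed to two decimals
truncated toward zero (the convention of field-report tables this module
reproduces), so a composed percentage can differ from the direct ratio by
up to a hundredth of a point.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal


class UndefinedTrialError(ValueError):
    """Raised when a trial has no weeds at all (rates undefined)."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate_pct(x: float, decimals: int = 2) -> float:
    """Truncate toward zero to the printed precision (86.2069 -> 86.20)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))


@dataclass(frozen=True)
class TrialCounts:
    """Raw counts from one trial strip."""

    n_total: int
    n_identified: int
    n_hit: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_hit <= self.n_identified <= self.n_total:
            raise ValueError(
                f"counts must satisfy 0 <= hits <= identified <= total, got "
                f"({self.n_total}, {self.n_identified}, {self.n_hit})")


@dataclass(frozen=True)
class TrialRates:
    """Unrounded rates in [0, 1]; ``degenerate`` flags n_identified == 0."""

    u: float
    w_rel: float
    w_abs: float
    degenerate: bool = False

    @property
    def u_pct(self) -> float:
        return truncate_pct(100.0 * self.u)

    @property
    def w_rel_pct(self) -> float:
        return truncate_pct(100.0 * self.w_rel)

    @property
    def w_abs_pct(self) -> float:
        return truncate_pct(100.0 * self.w_abs)


def rates_from_counts(c: TrialCounts) -> TrialRates:
    """Compute (u, w', w) from raw trial counts.

    ``w'`` for a trial with zero identifications is reported as 0 with the
    ``degenerate`` flag set.
    """
    if c.n_total == 0:
        raise UndefinedTrialError("trial with zero weeds has undefined rates")
    u = c.n_identified / c.n_total
    if c.n_identified == 0:
        return TrialRates(u=u, w_rel=0.0, w_abs=0.0, degenerate=True)
    return TrialRates(u=u, w_rel=c.n_hit / c.n_identified, w_abs=c.n_hit / c.n_total)


def compose_absolute(u: float, w_rel: float) -> float:
    """Absolute hit rate as the product of its two components."""
    if not (0.0 <= u <= 1.0 and 0.0 <= w_rel <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    return u * w_rel


def rates_table(rows: list[tuple[float, TrialCounts]]) -> "pandas.DataFrame":
    """Trial report, one row per forward speed, in the field-report layout."""
    import pandas as pd

    records = []
    for speed, counts in rows:
        r = rates_from_counts(counts)
        records.append({
            "speed_kmh": speed,
            "n_weeds": counts.n_total,
            "n_identified": counts.n_identified,
            "effective_recognition_rate_pct": r.u_pct,
            "n_hits": counts.n_hit,
            "relative_hit_rate_pct": r.w_rel_pct,
            "absolute_hit_rate_pct": r.w_abs_pct,
        })
    return pd.DataFrame.from_records(records)
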