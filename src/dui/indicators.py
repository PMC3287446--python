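"""The 14 basic usage indicators for one unit and analysis window.

Six absolute counts — searched records s(u), download frequency d(u),
record number r(u), search events S(u), download events D(u), dataset
number N(u) — and the normalized indicators derived from them:

    search density    s/S     records retrieved per search event
    download density  d/D     records downloaded per download event
    usage impact      d/r     downloads per stored record (UIF)
    interest impact   s/r     searches per stored record (IIF)
    usage ratio       d/s     share of searched records downloaded
    usage balance     D/S     share of search events leading to downloads
    usage score       100·U/r percent of stored records downloaded >= once
    interest score    100·I/r percent of stored records searched >= once

Every ratio with a zero denominator is undefined (None), never 0 or
infinity; scores are unavailable when the unique-record counts U/I are.
Internal values keep full precision; display rounding is half-up to two
decimals (three for the usage balance, matching how the ratio is printed).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

from .errors import ValidationError
from .eventlog import EventCounts, UsageEvent, count_events
from .registry import AnalysisWindow, Registry, Unit
from .rounding import round_half_up

__all__ = ["IndicatorSet", "compute_indicator_set", "usage_score", "time_series"]

#: display precision per derived indicator
_DISPLAY_DECIMALS = {
    "search_density": 2,
    "download_density": 2,
    "usage_impact": 2,
    "interest_impact": 2,
    "usage_ratio": 2,
    "usage_balance": 3,
    "usage_score": 2,
    "interest_score": 2,
}


@dataclass(frozen=True)
class IndicatorSet:
    """All 14 indicators for one (unit, window); None marks undefined or
    unavailable values."""

    unit_id: str
    window: str
    s: int
    d: int
    r: int
    S: int
    D: int
    N: int
    n: Optional[int] = None
    search_density: Optional[float] = None
    download_density: Optional[float] = None
    usage_impact: Optional[float] = None
    interest_impact: Optional[float] = None
    usage_ratio: Optional[float] = None
    usage_balance: Optional[float] = None
    usage_score: Optional[float] = None
    interest_score: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def rounded(self, balance_as_percent: bool = False) -> dict:
        """Display-rounded copy of as_dict(): half-up, two decimals, three
        for the usage balance (or two if rendered as a percent)."""
        out = self.as_dict()
        for name, nd in _DISPLAY_DECIMALS.items():
            v = out[name]
            if v is None:
                continue
            if name == "usage_balance" and balance_as_percent:
                v, nd = v * 100.0, 2
            out[name] = round_half_up(v, nd)
        return out


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den != 0 else None


def compute_indicator_set(
    counts: EventCounts, r: int, N: int
) -> IndicatorSet:
    """Derive the full indicator set from raw counts and denominators.

    counts supplies s, d, S, D (and optionally U, I, n); r is the stored
    record number and N the dataset number of the same unit and window.
    """
    if r < 0 or N < 0:
        raise ValidationError("negative denominator")
    return IndicatorSet(
        unit_id=counts.unit_id,
        window=counts.window,
        s=counts.s,
        d=counts.d,
        r=int(r),
        S=counts.S,
        D=counts.D,
        N=N,
        n=counts.n,
        search_density=_ratio(counts.s, counts.S),
        download_density=_ratio(counts.d, counts.D),
        usage_impact=_ratio(counts.d, r),
        interest_impact=_ratio(counts.s, r),
        usage_ratio=_ratio(counts.d, counts.s),
        usage_balance=_ratio(counts.D, counts.S),
        usage_score=usage_score(counts.U, r) if counts.U is not None else None,
        interest_score=usage_score(counts.I, r) if counts.I is not None else None,
    )


def usage_score(U: int, r: int) -> Optional[float]:
    """Percent of the unit's r stored records downloaded (or searched, for
    the interest score) at least once in the window: 100·U/r."""
    if r == 0:
        return None
    if not 0 <= U <= r:
        raise ValidationError(f"unique record count {U} outside [0, r={r}]")
    return 100.0 * U / r


def time_series(
    events: Sequence[UsageEvent],
    u: Unit | str,
    windows: Sequence[AnalysisWindow],
    registry: Registry,
) -> list[IndicatorSet]:
    """One IndicatorSet per window, with the unit's r(u) convention applied
    uniformly (the denominator snapshot is shared across windows)."""
    for i, a in enumerate(windows):
        for b in windows[i + 1:]:
            if a.overlaps(b):
                raise ValidationError(
                    f"overlapping windows: {a.label!r} and {b.label!r}"
                )
    unit = registry.unit(u) if isinstance(u, str) else u
    N = registry.dataset_number(unit)
    out = []
    for w in windows:
        r = registry.record_number(unit, w)
        counts = count_events(events, unit, w, registry)
        out.append(compute_indicator_set(counts, int(r), N))
    return out
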