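"""Relative and species-profile-weighted comparative indices.

Absolute impact factors only become interpretable against a baseline. The
relative usage-impact index divides a unit's UIF = d(u)/r(u) by the
baseline aggregate's impact Σd_i / Σr_i over the n baseline units — a
*ratio of sums*, so large datasets weight more than a mean of per-unit
ratios would. The same formula with searched records s in place of d gives
the relative interest-impact (IIF) index. An index of 1.0 means the unit
performs exactly at the baseline level.

The Usage Crown Indicator (UCI) field-normalizes by the unit's species
profile: observed downloads d(u) over the downloads expected if each of the
unit's species were used at its global per-species rate,

    UCI = d(u) / Σ_{s=1..p} r_s · U_s,      U_s = Σ_i d_s,i / Σ_i r_s,i

where r_s are the unit's stored records per species, p the number of
profile species, and U_s the expected global per-species UIF over the n
reference units (again a ratio of sums). UCI = 1.0 means usage on par with
the global (or regional) baseline given the unit's own species mix.

Two rounding modes exist for the relative index: "full" (default) divides
full-precision impact factors; "paper" first rounds each absolute UIF
half-up to two decimals, reproducing indices as printed in two-decimal
tables (e.g. 6.50/0.32 = 20.31, where full precision gives 19.99).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import OrphanSpeciesError, ValidationError
from .rounding import round_half_up

__all__ = [
    "SpeciesProfile",
    "SpeciesBaseline",
    "relative_index",
    "species_baseline",
    "usage_crown_indicator",
    "brute_force_adjust",
    "read_profiles",
]

DRPair = tuple[float, float]  # (downloaded or searched records, stored records)


@dataclass(frozen=True)
class SpeciesProfile:
    """A unit's distribution of stored records and downloads over species.

    entries maps species name -> (r_s stored records, d_s downloaded
    records); p is the number of distinct species actually stocked
    (r_s > 0).
    """

    unit_id: str
    entries: Mapping[str, DRPair] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, (r_s, d_s) in self.entries.items():
            if r_s < 0 or d_s < 0:
                raise ValidationError(f"{self.unit_id}/{sp}: negative counts")

    @property
    def p(self) -> int:
        return sum(1 for r_s, _ in self.entries.values() if r_s > 0)

    @property
    def d_total(self) -> float:
        return sum(d_s for _, d_s in self.entries.values())

    @property
    def r_total(self) -> float:
        return sum(r_s for r_s, _ in self.entries.values())


@dataclass(frozen=True)
class SpeciesBaseline:
    """Expected global per-species UIF values U_s over n reference units.

    Species with zero global stored records are absent (their expected
    impact is undefined, not zero).
    """

    expected_uif: Mapping[str, float]
    n_units: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.expected_uif.values()):
            raise ValidationError("negative expected UIF")

    def __getitem__(self, species: str) -> float:
        return self.expected_uif[species]

    def __contains__(self, species: str) -> bool:
        return species in self.expected_uif


def relative_index(
    unit: Union[float, DRPair],
    baseline_units: Sequence[DRPair],
    rounding: str = "full",
) -> Optional[float]:
    """Unit impact factor over the ratio-of-sums baseline impact factor.

    unit is either a precomputed impact factor or a (d, r) pair; the
    baseline is Σd_i / Σr_i over the baseline (d_i, r_i) pairs. Passing
    searched records s for d yields the relative IIF. Returns None
    (undefined) when the baseline holds no records.

    rounding="paper" rounds both impact factors half-up to two decimals
    before dividing and rounds the index to two decimals, matching printed
    two-decimal tables; "full" keeps full precision.
    """
    if rounding not in ("full", "paper"):
        raise ValidationError(f"unknown rounding mode {rounding!r}")
    sum_d = float(sum(d for d, _ in baseline_units))
    sum_r = float(sum(r for _, r in baseline_units))
    if sum_r == 0:
        return None
    baseline = sum_d / sum_r
    if isinstance(unit, tuple):
        d_u, r_u = unit
        if r_u == 0:
            return None
        value = d_u / r_u
    else:
        value = float(unit)
    if rounding == "paper":
        value = round_half_up(value, 2)
        baseline = round_half_up(baseline, 2)
    if baseline == 0:
        return None
    index = value / baseline
    return round_half_up(index, 2) if rounding == "paper" else index


def species_baseline(profiles: Iterable[SpeciesProfile]) -> SpeciesBaseline:
    """Aggregate reference profiles into expected global per-species UIFs.

    For each species, U_s = Σ_units d_s / Σ_units r_s (ratio of sums).
    Species stocked nowhere (Σ r_s = 0) are omitted with a warning.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("species_baseline needs at least one profile")
    sum_r: dict[str, float] = {}
    sum_d: dict[str, float] = {}
    for prof in profiles:
        for sp, (r_s, d_s) in prof.entries.items():
            sum_r[sp] = sum_r.get(sp, 0.0) + r_s
            sum_d[sp] = sum_d.get(sp, 0.0) + d_s
    expected: dict[str, float] = {}
    for sp in sum_r:
        if sum_r[sp] == 0:
            warnings.warn(
                f"species {sp!r} has zero stored records globally; omitted "
                "from baseline",
                stacklevel=2,
            )
            continue
        expected[sp] = sum_d[sp] / sum_r[sp]
    return SpeciesBaseline(expected_uif=expected, n_units=len(profiles))


def usage_crown_indicator(
    profile: SpeciesProfile,
    baseline: SpeciesBaseline,
    d_total: Optional[float] = None,
) -> Optional[float]:
    """Observed over species-profile-expected downloads.

    The expected downloads are Σ r_s · U_s over the profile's p stocked
    species. d_total defaults to the profile's summed per-species
    downloads; pass it explicitly when the unit's total download frequency
    is known independently of the species breakdown. Returns None when the
    expected sum is zero. Profile species missing from the baseline are a
    hard error: skipping them silently would change p and bias the index.
    """
    stocked = {sp: rd for sp, rd in profile.entries.items() if rd[0] > 0}
    orphans = [sp for sp in stocked if sp not in baseline]
    if orphans:
        raise OrphanSpeciesError(orphans)
    expected = sum(r_s * baseline[sp] for sp, (r_s, _) in stocked.items())
    if d_total is None:
        d_total = profile.d_total
    if expected == 0:
        return None
    return d_total / expected


def brute_force_adjust(value: float, r: float) -> float:
    """Size adjustment for cross-size comparisons: multiply a normalized
    impact factor by the unit's stored records in millions, separating
    ultra-large publishers from the rest."""
    if r < 0:
        raise ValidationError("r < 0")
    return value * (r / 1_000_000.0)


def write_profiles(
    profiles: Iterable[SpeciesProfile], path: str | Path
) -> None:
    """Write species profiles as long CSV unit_id,species,records,downloads."""
    rows = [
        {"unit_id": p.unit_id, "species": sp, "records": r_s, "downloads": d_s}
        for p in profiles
        for sp, (r_s, d_s) in sorted(p.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[SpeciesProfile]:
    """Read species profiles from long CSV unit_id,species,records,downloads."""
    df = pd.read_csv(path, dtype={"unit_id": str, "species": str})
    required = {"unit_id", "species", "records", "downloads"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"profile file missing columns: {sorted(missing)}")
    out = []
    for uid, grp in df.groupby("unit_id", sort=True):
        entries = {
            row.species: (float(row.records), float(row.downloads))
            for row in grp.itertuples(index=False)
        }
        out.append(SpeciesProfile(unit_id=str(uid), entries=entries))
    return out
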