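"""Analysis units and stored-record inventories.

A *unit* is anything indicators are computed for: a single dataset, a data
publisher, a country, a region, an ad-hoc species slice, or the world (the
union of everything registered). The registry maps every unit to its member
datasets and supplies the two denominators the normalized indicators need:
the stored-record number r(u) and the dataset number N(u).

Record counting across aggregated datasets deduplicates shared records only
when explicit record ids are available for every member dataset; otherwise
the plain sum is returned and flagged as potentially overcounting. (National
totals can be smaller than the sum over publishers precisely because of such
cross-dataset duplicates.)
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import DuplicateDatasetError, UnknownUnitError, ValidationError

__all__ = [
    "DatasetInventory",
    "Unit",
    "Level",
    "AnalysisWindow",
    "Registry",
    "RecordCount",
    "SizeClass",
    "SIZE_CLASS_BOUNDS",
    "build_registry",
    "read_inventory",
]

_ISO2 = re.compile(r"^[A-Z]{2}$")


class Level(str, Enum):
    DATASET = "dataset"
    PUBLISHER = "publisher"
    COUNTRY = "country"
    REGION = "region"
    SPECIES_SLICE = "species_slice"
    WORLD = "world"


class SizeClass(str, Enum):
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"
    ULTRA_LARGE = "ultra_large"


#: Publisher size classes by dataset number N(u). The verbal ranges
#: ("less than 10", "10-100", "100-300", "over 300") overlap at the
#: boundaries; the convention adopted here is half-open at 10 and
#: inclusive upper bounds at 100 and 300.
SIZE_CLASS_BOUNDS: tuple[tuple[int, SizeClass], ...] = (
    (10, SizeClass.SMALL),  # N < 10
    (101, SizeClass.MEDIUM),  # 10 <= N <= 100
    (301, SizeClass.LARGE),  # 101 <= N <= 300
)


@dataclass(frozen=True)
class DatasetInventory:
    """Stored-record inventory of one dataset at a snapshot instant.

    species_records maps controlled species names to stored-record counts;
    it may be partial, in which case total_records exceeds its sum.
    record_ids, when present, enable exact duplicate handling and the
    unique-record usage/interest scores.
    """

    dataset_id: str
    publisher_id: str
    country_code: str
    total_records: int
    region: Optional[str] = None
    species_records: Mapping[str, int] = field(default_factory=dict)
    record_ids: Optional[frozenset[str]] = None
    byte_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.total_records < 0:
            raise ValidationError(f"{self.dataset_id}: total_records < 0")
        if any(v < 0 for v in self.species_records.values()):
            raise ValidationError(f"{self.dataset_id}: negative species record count")
        species_sum = sum(self.species_records.values())
        if self.total_records < species_sum:
            raise ValidationError(
                f"{self.dataset_id}: total_records ({self.total_records}) < "
                f"sum of species records ({species_sum})"
            )
        if self.record_ids is not None and len(self.record_ids) != self.total_records:
            raise ValidationError(
                f"{self.dataset_id}: |record_ids| ({len(self.record_ids)}) != "
                f"total_records ({self.total_records})"
            )
        if self.byte_size is not None and self.byte_size < 0:
            raise ValidationError(f"{self.dataset_id}: byte_size < 0")


@dataclass(frozen=True)
class Unit:
    """An aggregation entity indicators are computed for."""

    unit_id: str
    level: Level
    member_datasets: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.unit_id)


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open UTC time interval [start, end) used for event counting.

    record_count_convention picks which r(u) snapshot normalizes the window:
    the count at the end of the window (default, matching the fixed
    end-of-year denominators of the worked examples), the current count, or
    the average over the window. With a single inventory snapshot all three
    coincide.
    """

    start: datetime
    end: datetime
    label: str = ""
    record_count_convention: str = "end_of_window"

    def __post_init__(self) -> None:
        start, end = (_as_utc(self.start), _as_utc(self.end))
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if not start < end:
            raise ValidationError(f"window start {start} not before end {end}")
        if self.record_count_convention not in (
            "end_of_window",
            "current",
            "window_average",
        ):
            raise ValidationError(
                f"unknown record_count_convention {self.record_count_convention!r}"
            )
        if not self.label:
            object.__setattr__(
                self, "label", f"{start:%Y-%m-%d}:{end:%Y-%m-%d}"
            )

    def __contains__(self, ts: datetime) -> bool:
        return self.start <= _as_utc(ts) < self.end

    def overlaps(self, other: "AnalysisWindow") -> bool:
        return self.start < other.end and other.start < self.end


def _as_utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


class RecordCount(int):
    """Integer record number r(u) carrying a deduplication flag.

    deduplicated is True when cross-dataset duplicates were counted once
    (record ids were available for all member datasets); False means the
    value is a plain sum that may overcount shared records.
    """

    deduplicated: bool

    def __new__(cls, value: int, deduplicated: bool) -> "RecordCount":
        obj = super().__new__(cls, value)
        obj.deduplicated = deduplicated
        return obj


class Registry:
    """Holds dataset inventories and the derived analysis units."""

    def __init__(self, inventories: Iterable[DatasetInventory] = ()):
        self._inventories: dict[str, DatasetInventory] = {}
        self._units: dict[str, Unit] = {}
        for inv in inventories:
            if inv.dataset_id in self._inventories:
                raise DuplicateDatasetError(
                    f"duplicate dataset_id: {inv.dataset_id!r}"
                )
            if not _ISO2.match(inv.country_code or ""):
                warnings.warn(
                    f"dataset {inv.dataset_id}: country code "
                    f"{inv.country_code!r} is not ISO-3166 alpha-2; "
                    "unit built anyway",
                    stacklevel=3,
                )
            self._inventories[inv.dataset_id] = inv
        self._build_units()

    # -- construction -----------------------------------------------------

    def _build_units(self) -> None:
        units: dict[str, Unit] = {}
        by_publisher: dict[str, set[str]] = {}
        by_country: dict[str, set[str]] = {}
        by_region: dict[str, set[str]] = {}
        for inv in self._inventories.values():
            units[f"dataset:{inv.dataset_id}"] = Unit(
                f"dataset:{inv.dataset_id}", Level.DATASET,
                frozenset({inv.dataset_id}), inv.dataset_id,
            )
            by_publisher.setdefault(inv.publisher_id, set()).add(inv.dataset_id)
            by_country.setdefault(inv.country_code, set()).add(inv.dataset_id)
            if inv.region:
                by_region.setdefault(inv.region, set()).add(inv.dataset_id)
        for pid, members in by_publisher.items():
            units[f"publisher:{pid}"] = Unit(
                f"publisher:{pid}", Level.PUBLISHER, frozenset(members), pid
            )
        for cc, members in by_country.items():
            units[f"country:{cc}"] = Unit(
                f"country:{cc}", Level.COUNTRY, frozenset(members), cc
            )
        for reg, members in by_region.items():
            units[f"region:{reg}"] = Unit(
                f"region:{reg}", Level.REGION, frozenset(members), reg
            )
        units["world"] = Unit(
            "world", Level.WORLD, frozenset(self._inventories), "world"
        )
        self._units = units

    def add_species_slice(self, slice_id: str, species: Iterable[str]) -> Unit:
        """Register a unit of all datasets holding records of any listed species."""
        wanted = set(species)
        members = frozenset(
            ds for ds, inv in self._inventories.items()
            if wanted & {s for s, n in inv.species_records.items() if n > 0}
        )
        unit = Unit(f"species_slice:{slice_id}", Level.SPECIES_SLICE, members, slice_id)
        self._units[unit.unit_id] = unit
        return unit

    # -- lookup -----------------------------------------------------------

    @property
    def inventories(self) -> Mapping[str, DatasetInventory]:
        return dict(self._inventories)

    @property
    def units(self) -> Mapping[str, Unit]:
        return dict(self._units)

    def unit(self, unit_id: str) -> Unit:
        try:
            return self._units[unit_id]
        except KeyError:
            raise UnknownUnitError(unit_id) from None

    def units_at(self, level: Level | str) -> list[Unit]:
        level = Level(level)
        return sorted(
            (u for u in self._units.values() if u.level == level),
            key=lambda u: u.unit_id,
        )

    # -- denominators -----------------------------------------------------

    def record_number(
        self, u: Unit | str, window: Optional[AnalysisWindow] = None
    ) -> RecordCount:
        """r(u): stored records in the unit under the window's convention.

        With one inventory snapshot every convention yields the same value;
        the window argument is accepted so callers can pass their analysis
        window uniformly.
        """
        unit = self.unit(u) if isinstance(u, str) else u
        if unit.unit_id not in self._units:
            raise UnknownUnitError(unit.unit_id)
        invs = [self._inventories[ds] for ds in unit.member_datasets]
        if not invs:
            return RecordCount(0, True)
        if all(inv.record_ids is not None for inv in invs):
            ids: set[str] = set()
            for inv in invs:
                ids |= inv.record_ids  # type: ignore[arg-type]
            return RecordCount(len(ids), True)
        return RecordCount(sum(inv.total_records for inv in invs), False)

    def dataset_number(self, u: Unit | str) -> int:
        """N(u): number of member datasets."""
        unit = self.unit(u) if isinstance(u, str) else u
        return len(unit.member_datasets)

    def size_class(self, u: Unit | str) -> SizeClass:
        """Publisher size class from N(u)."""
        unit = self.unit(u) if isinstance(u, str) else u
        if unit.level != Level.PUBLISHER:
            raise ValidationError(
                f"size_class applies to publisher units, got {unit.level.value}"
            )
        n = self.dataset_number(unit)
        for bound, cls in SIZE_CLASS_BOUNDS:
            if n < bound:
                return cls
        return SizeClass.ULTRA_LARGE

    def dataset_to_units(self) -> dict[str, list[str]]:
        """Map each dataset_id to the unit_ids containing it."""
        out: dict[str, list[str]] = {ds: [] for ds in self._inventories}
        for unit in self._units.values():
            for ds in unit.member_datasets:
                out[ds].append(unit.unit_id)
        return out


def build_registry(inventories: Iterable[DatasetInventory]) -> Registry:
    """Build the unit registry: one unit per dataset, publisher, country and
    region present, plus a world unit over everything."""
    return Registry(inventories)


def read_inventory(
    inventory_csv: str | Path,
    species_csv: str | Path | None = None,
    record_ids_csv: str | Path | None = None,
) -> list[DatasetInventory]:
    """Read inventories from the CSV dialect.

    inventory_csv columns: dataset_id, publisher_id, country_code,
    [region], total_records, [byte_size]; unknown (e.g. Darwin Core
    metadata) columns are ignored. species_csv is long-format
    dataset_id,species,records; record_ids_csv is dataset_id,record_id.
    """
    df = pd.read_csv(inventory_csv, dtype={"dataset_id": str, "publisher_id": str})
    required = {"dataset_id", "publisher_id", "country_code", "total_records"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"inventory file missing columns: {sorted(missing)}")

    species: dict[str, dict[str, int]] = {}
    if species_csv is not None:
        sp = pd.read_csv(species_csv, dtype={"dataset_id": str, "species": str})
        for ds, grp in sp.groupby("dataset_id"):
            species[str(ds)] = dict(
                zip(grp["species"], grp["records"].astype(int))
            )
    ids: dict[str, frozenset[str]] = {}
    if record_ids_csv is not None:
        rid = pd.read_csv(record_ids_csv, dtype=str)
        for ds, grp in rid.groupby("dataset_id"):
            ids[str(ds)] = frozenset(grp["record_id"])

    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ds = str(d["dataset_id"])
        region = d.get("region")
        byte_size = d.get("byte_size")
        out.append(
            DatasetInventory(
                dataset_id=ds,
                publisher_id=str(d["publisher_id"]),
                country_code=str(d["country_code"]),
                total_records=int(d["total_records"]),
                region=None if pd.isna(region) else str(region),
                species_records=species.get(ds, {}),
                record_ids=ids.get(ds),
                byte_size=None if byte_size is None or pd.isna(byte_size)
                else int(byte_size),
            )
        )
    return out
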