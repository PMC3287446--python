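"""Synthetic inventories and usage-event streams for end-to-end testing.

The generator emulates the structure of a biodiversity data-portal usage
log: publishers in countries publish heavy-tailed numbers of datasets with
heavy-tailed record counts and individual species profiles; anonymized
visitors search, view and download records in sessions, and roughly
two-thirds of raw events are metadata-only bounces. Default magnitudes
follow the portal statistics the indicators were designed around: a bounce
fraction near 0.66, search events retrieving a few tens of records,
download events a few hundred, and download events forming roughly 1-2% of
search events.

Alongside the files, generate() returns the exact per-unit counts it
injected (s, d, S, D, U, I, n per dataset, publisher, country and world),
so the whole counting pipeline can be tested against ground truth.

Randomness uses one root seed; every consumer draws from its own named
substream, so adding a consumer never perturbs the streams of existing
ones and a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .eventlog import UsageEvent
from .registry import AnalysisWindow, DatasetInventory

__all__ = [
    "SimConfig",
    "SimResult",
    "generate",
    "write_outputs",
    "species_usage_profiles",
]

_COUNTRIES = ("DK", "NO", "SE", "DE", "GB", "FR", "NL", "ES")
_REGIONS = {"DK": "Nordics", "NO": "Nordics", "SE": "Nordics"}

#: distribution specs: {"dist": name, ...params}; supported names below
_DISTS = ("constant", "poisson", "lognormal", "zipf", "geometric")


def _default_window() -> AnalysisWindow:
    return AnalysisWindow(
        datetime(2009, 7, 1, tzinfo=timezone.utc),
        datetime(2010, 1, 1, tzinfo=timezone.utc),
        label="2009b",
    )


@dataclass
class SimConfig:
    """Study conditions for one synthetic portal log.

    Distribution specs are dicts {"dist": ..., params...}; samples are
    clipped to [1, max] where a "max" key is present. Defaults are
    desk-scale (tens of publishers, ~1e5 records, ~1e4 raw events) and
    calibrated to the portal magnitudes described in the module docstring.
    """

    n_publishers: int = 20
    datasets_per_publisher: dict = field(
        default_factory=lambda: {"dist": "zipf", "a": 1.8, "max": 30}
    )
    records_per_dataset: dict = field(
        default_factory=lambda: {
            "dist": "lognormal", "mu": 5.5, "sigma": 2.0, "max": 50_000,
        }
    )
    n_species: int = 150
    species_concentration: float = 0.3
    n_ips: int = 400
    events_per_ip: dict = field(
        default_factory=lambda: {"dist": "poisson", "lam": 25}
    )
    bounce_fraction: float = 0.66
    session_gap_minutes: float = 30.0
    download_given_search: float = 0.014
    taxonomy_download_fraction: float = 0.1
    records_per_search_event: dict = field(
        default_factory=lambda: {"dist": "lognormal", "mu": 3.0, "sigma": 0.8}
    )
    records_per_download_event: dict = field(
        default_factory=lambda: {"dist": "lognormal", "mu": 5.5, "sigma": 0.8}
    )
    window: AnalysisWindow = field(default_factory=_default_window)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_publishers", "n_species", "n_ips"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in (
            "bounce_fraction", "download_given_search",
            "taxonomy_download_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.session_gap_minutes <= 0:
            raise ValidationError("session_gap_minutes must be positive")
        if self.species_concentration <= 0:
            raise ValidationError("species_concentration must be positive")
        for name in (
            "datasets_per_publisher", "records_per_dataset", "events_per_ip",
            "records_per_search_event", "records_per_download_event",
        ):
            spec = getattr(self, name)
            if spec.get("dist") not in _DISTS:
                raise ValidationError(
                    f"{name}: unknown distribution {spec.get('dist')!r}"
                )


@dataclass
class SimResult:
    inventories: list[DatasetInventory]
    events: list[UsageEvent]
    ground_truth: dict
    config: SimConfig


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


def _sample(rng: np.random.Generator, spec: dict, size: int) -> np.ndarray:
    dist = spec["dist"]
    if dist == "constant":
        x = np.full(size, float(spec["value"]))
    elif dist == "poisson":
        x = rng.poisson(spec["lam"], size).astype(float)
    elif dist == "lognormal":
        x = rng.lognormal(spec["mu"], spec["sigma"], size)
    elif dist == "zipf":
        x = rng.zipf(spec["a"], size).astype(float)
    elif dist == "geometric":
        x = rng.geometric(spec["p"], size).astype(float)
    else:  # pragma: no cover - guarded by validate()
        raise ValidationError(f"unknown distribution {dist!r}")
    x = np.maximum(1, np.rint(x))
    if "max" in spec:
        x = np.minimum(x, spec["max"])
    return x.astype(int)


def generate(config: SimConfig) -> SimResult:
    """Generate (inventories, event stream, ground truth) for one config."""
    config.validate()
    inventories = _make_inventories(config)
    sizes = {inv.dataset_id: inv.total_records for inv in inventories}

    for name in ("records_per_search_event", "records_per_download_event"):
        spec = getattr(config, name)
        if spec["dist"] == "constant" and spec["value"] > max(sizes.values()):
            raise ValidationError(
                f"{name} requests {spec['value']} records but the largest "
                f"dataset holds {max(sizes.values())}"
            )

    events, per_ds = _make_events(config, inventories)

    ground_truth = _aggregate_ground_truth(config, inventories, events, per_ds)
    return SimResult(
        inventories=inventories, events=events,
        ground_truth=ground_truth, config=config,
    )


def _make_inventories(config: SimConfig) -> list[DatasetInventory]:
    seed = config.seed
    rng_inv = _rng(seed, "inventory")
    rng_sp = _rng(seed, "species")
    n_datasets = _sample(
        rng_inv, config.datasets_per_publisher, config.n_publishers
    )
    species_names = [f"species{j:04d}" for j in range(config.n_species)]
    inventories = []
    ds_idx = 0
    for p in range(config.n_publishers):
        pid = f"P{p:03d}"
        country = _COUNTRIES[p % len(_COUNTRIES)]
        region = _REGIONS.get(country, "Western Europe")
        records = _sample(rng_inv, config.records_per_dataset, n_datasets[p])
        for r_ds in records:
            ds = f"D{ds_idx:04d}"
            ds_idx += 1
            # each dataset has its own species profile; a small
            # concentration parameter concentrates records on few species
            weights = rng_sp.dirichlet(
                np.full(config.n_species, config.species_concentration)
            )
            counts = rng_sp.multinomial(int(r_ds), weights)
            species_records = {
                sp: int(c) for sp, c in zip(species_names, counts) if c > 0
            }
            inventories.append(
                DatasetInventory(
                    dataset_id=ds,
                    publisher_id=pid,
                    country_code=country,
                    region=region,
                    total_records=int(r_ds),
                    species_records=species_records,
                    record_ids=frozenset(
                        f"{ds}:{i}" for i in range(int(r_ds))
                    ),
                )
            )
    return inventories


def _make_events(config: SimConfig, inventories: list[DatasetInventory]):
    seed = config.seed
    rng_t = _rng(seed, "timing")
    rng_e = _rng(seed, "events")
    window = config.window
    span = (window.end - window.start).total_seconds()
    ds_ids = [inv.dataset_id for inv in inventories]
    sizes = np.array([inv.total_records for inv in inventories], dtype=float)
    popularity = sizes / sizes.sum()

    n_events = _sample(rng_t, config.events_per_ip, config.n_ips)
    events: list[UsageEvent] = []
    per_ds: dict[str, dict] = {
        ds: {"s": 0, "d": 0, "S": 0, "D": 0,
             "searched": set(), "downloaded": set()}
        for ds in ds_ids
    }

    for i in range(config.n_ips):
        ip = f"ip{i:05d}"
        # sessionized arrival process: short in-session gaps, occasional
        # long (>= gap rule) pauses starting new sessions
        t = window.start + timedelta(seconds=float(rng_t.uniform(0, span * 0.9)))
        for _ in range(n_events[i]):
            if t >= window.end:
                break
            if rng_e.random() < config.bounce_fraction:
                ds = ds_ids[rng_e.choice(len(ds_ids), p=popularity)] \
                    if rng_e.random() < 0.7 else None
                events.append(UsageEvent(t, ip, "metadata_view", ds, 0))
            else:
                k = rng_e.choice(len(ds_ids), p=popularity)
                ds = ds_ids[k]
                size = int(sizes[k])
                touched = int(min(
                    _sample(rng_e, config.records_per_search_event, 1)[0],
                    size,
                ))
                ids = frozenset(
                    f"{ds}:{j}"
                    for j in rng_e.choice(size, touched, replace=False)
                )
                etype = "search" if rng_e.random() < 0.7 else "view"
                events.append(UsageEvent(t, ip, etype, ds, touched, ids))
                acc = per_ds[ds]
                acc["s"] += touched
                acc["S"] += 1
                acc["searched"] |= ids
                if rng_e.random() < config.download_given_search:
                    td = t + timedelta(seconds=10)
                    if td < window.end:
                        dl = int(min(
                            _sample(
                                rng_e, config.records_per_download_event, 1
                            )[0],
                            size,
                        ))
                        dids = frozenset(
                            f"{ds}:{j}"
                            for j in rng_e.choice(size, dl, replace=False)
                        )
                        dtype = (
                            "taxonomy_download"
                            if rng_e.random() < config.taxonomy_download_fraction
                            else "download"
                        )
                        events.append(UsageEvent(td, ip, dtype, ds, dl, dids))
                        acc["d"] += dl
                        acc["D"] += 1
                        acc["downloaded"] |= dids
            if rng_t.random() < 0.15:
                gap = config.session_gap_minutes + float(rng_t.exponential(120.0))
            else:
                gap = float(rng_t.exponential(4.0))
            t = t + timedelta(minutes=gap)
    events.sort(key=lambda e: (e.timestamp, e.ip_key))
    return events, per_ds


def _aggregate_ground_truth(config, inventories, events, per_ds) -> dict:
    groups: dict[str, list[str]] = {"world": [inv.dataset_id for inv in inventories]}
    for inv in inventories:
        groups[f"dataset:{inv.dataset_id}"] = [inv.dataset_id]
        groups.setdefault(f"publisher:{inv.publisher_id}", []).append(inv.dataset_id)
        groups.setdefault(f"country:{inv.country_code}", []).append(inv.dataset_id)
        groups.setdefault(f"region:{inv.region}", []).append(inv.dataset_id)
    units = {}
    for uid, members in groups.items():
        s = sum(per_ds[ds]["s"] for ds in members)
        d = sum(per_ds[ds]["d"] for ds in members)
        S = sum(per_ds[ds]["S"] for ds in members)
        D = sum(per_ds[ds]["D"] for ds in members)
        searched: set = set().union(*(per_ds[ds]["searched"] for ds in members))
        downloaded: set = set().union(*(per_ds[ds]["downloaded"] for ds in members))
        n_used = sum(
            1 for ds in members if per_ds[ds]["S"] + per_ds[ds]["D"] > 0
        )
        units[uid] = {
            "s": s, "d": d, "S": S, "D": D,
            "U": len(downloaded), "I": len(searched), "n": n_used,
        }
    n_bounce = sum(
        1 for e in events
        if e.event_type == "metadata_view"
        or (e.event_type in ("search", "view") and e.records_touched == 0)
    )
    return {
        "units": units,
        "n_events": len(events),
        "n_bounces": n_bounce,
        "bounce_fraction": n_bounce / len(events) if events else 0.0,
        "window": config.window.label,
        "seed": config.seed,
    }


def species_usage_profiles(
    result: SimResult, level: str = "publisher"
) -> dict[str, "SpeciesProfile"]:
    """Roll download events up into per-unit species profiles.

    Within a dataset, record ids are assigned to species in sorted species
    order ("D0001:0".."D0001:r-1" partitioned by the species_records
    counts), so every downloaded id maps deterministically to a species.
    Returns one SpeciesProfile per unit at the requested level (dataset,
    publisher, country, region or world), with r_s the unit's stored
    records and d_s its downloaded records per species.
    """
    from .comparative import SpeciesProfile
    from .eventlog import DOWNLOAD_TYPES

    def unit_of(inv: DatasetInventory) -> str:
        if level == "dataset":
            return f"dataset:{inv.dataset_id}"
        if level == "publisher":
            return f"publisher:{inv.publisher_id}"
        if level == "country":
            return f"country:{inv.country_code}"
        if level == "region":
            return f"region:{inv.region}"
        if level == "world":
            return "world"
        raise ValidationError(f"unknown level {level!r}")

    by_ds = {inv.dataset_id: inv for inv in result.inventories}
    # species boundaries per dataset, in sorted species order
    bounds: dict[str, tuple[list[str], np.ndarray]] = {}
    for ds, inv in by_ds.items():
        names = sorted(inv.species_records)
        cum = np.cumsum([inv.species_records[sp] for sp in names])
        bounds[ds] = (names, cum)

    entries: dict[str, dict[str, list[float]]] = {}
    for inv in by_ds.values():
        uid = unit_of(inv)
        unit_entries = entries.setdefault(uid, {})
        for sp, r_s in inv.species_records.items():
            rd = unit_entries.setdefault(sp, [0.0, 0.0])
            rd[0] += r_s
    for e in result.events:
        if e.event_type not in DOWNLOAD_TYPES or not e.record_ids:
            continue
        inv = by_ds[e.dataset_id]
        uid = unit_of(inv)
        names, cum = bounds[e.dataset_id]
        idx = np.array([int(rid.split(":", 1)[1]) for rid in e.record_ids])
        for j in np.searchsorted(cum, idx, side="right"):
            entries[uid][names[j]][1] += 1.0
    return {
        uid: SpeciesProfile(
            unit_id=uid, entries={sp: (rd[0], rd[1]) for sp, rd in sps.items()}
        )
        for uid, sps in entries.items()
    }


def write_outputs(
    result: SimResult, outdir: str | Path, record_ids: bool = False
) -> dict[str, Path]:
    """Write inventory.csv, species.csv, events.csv and ground_truth.json
    in the file dialects the registry and eventlog readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    inv_rows = [
        {
            "dataset_id": inv.dataset_id,
            "publisher_id": inv.publisher_id,
            "country_code": inv.country_code,
            "region": inv.region,
            "total_records": inv.total_records,
            "byte_size": "",
        }
        for inv in result.inventories
    ]
    paths["inventory"] = outdir / "inventory.csv"
    pd.DataFrame(inv_rows).to_csv(paths["inventory"], index=False)

    sp_rows = [
        {"dataset_id": inv.dataset_id, "species": sp, "records": n}
        for inv in result.inventories
        for sp, n in sorted(inv.species_records.items())
    ]
    paths["species"] = outdir / "species.csv"
    pd.DataFrame(sp_rows).to_csv(paths["species"], index=False)

    ev_rows = [
        {
            "timestamp": e.timestamp.isoformat(),
            "ip_key": e.ip_key,
            "event_type": e.event_type,
            "dataset_id": e.dataset_id or "",
            "records_touched": e.records_touched,
            "record_ids": ";".join(sorted(e.record_ids)) if record_ids and e.record_ids else "",
        }
        for e in result.events
    ]
    paths["events"] = outdir / "events.csv"
    pd.DataFrame(ev_rows).to_csv(paths["events"], index=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(
        json.dumps(result.ground_truth, indent=1, sort_keys=True)
    )
    return paths
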