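"""Batch computation runs and the annual usage report.

run_compute executes the full pipeline (inventory -> registry -> bounce
filter -> per-window counts -> indicator sets) for a declarative RunConfig
and freezes a snapshot manifest (input digests + config echo + version) so
any report number can be recomputed bit-exactly later; re-running under an
existing snapshot label with changed inputs fails loudly.

annual_report produces the usage analogue of a journal citation report: one
row per publisher with N, n, r, s, d, UIF, IIF, optional UCI, size class
and rank by UIF (ties broken by r descending, then unit_id).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .comparative import SpeciesBaseline, SpeciesProfile, usage_crown_indicator
from .errors import SnapshotMismatchError, ValidationError
from .eventlog import filter_bounces, parse_events
from .indicators import IndicatorSet, time_series
from .registry import AnalysisWindow, Level, Registry, build_registry, read_inventory

__all__ = ["RunConfig", "run_compute", "annual_report"]


@dataclass
class RunConfig:
    inventory_csv: Path
    events_csv: Path
    windows: list[AnalysisWindow]
    out_dir: Path
    species_csv: Optional[Path] = None
    levels: Sequence[str] = ("publisher",)
    unit_ids: Optional[Sequence[str]] = None
    rounding: str = "full"
    baseline_scope: str = "world"
    snapshot_label: str = "snapshot"
    balance_as_percent: bool = False

    def __post_init__(self) -> None:
        for p in (self.inventory_csv, self.events_csv, self.species_csv):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")
        if not self.windows:
            raise ValidationError("at least one analysis window required")


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_compute(config: RunConfig) -> dict[str, Path]:
    """Compute indicator sets per window and unit; write CSV + JSON + a
    frozen snapshot manifest. Returns the written paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "tool": "dui",
        "version": __version__,
        "snapshot_label": config.snapshot_label,
        "inputs": {
            "inventory": _digest(config.inventory_csv),
            "events": _digest(config.events_csv),
            **(
                {"species": _digest(config.species_csv)}
                if config.species_csv else {}
            ),
        },
        "windows": [
            {"start": w.start.isoformat(), "end": w.end.isoformat(),
             "label": w.label,
             "record_count_convention": w.record_count_convention}
            for w in config.windows
        ],
        "levels": list(config.levels),
        "rounding": config.rounding,
        "baseline_scope": config.baseline_scope,
    }
    manifest_path = out / f"{config.snapshot_label}.manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("inputs") != manifest["inputs"]:
            raise SnapshotMismatchError(
                f"inputs changed under snapshot {config.snapshot_label!r}; "
                "refusing to overwrite"
            )

    inventories = read_inventory(config.inventory_csv, config.species_csv)
    registry = build_registry(inventories)
    parsed = parse_events(config.events_csv)
    kept, bounce_fraction = filter_bounces(parsed.events)

    units = []
    if config.unit_ids:
        units = [registry.unit(uid) for uid in config.unit_ids]
    else:
        for level in config.levels:
            units.extend(registry.units_at(Level(level)))
    if not kept:
        import warnings

        warnings.warn("no usable events after bounce filtering", stacklevel=2)

    rows = []
    for unit in units:
        for ind in time_series(kept, unit, config.windows, registry):
            rows.append(ind.rounded(config.balance_as_percent))
    df = pd.DataFrame(rows)
    paths = {"manifest": manifest_path}
    paths["csv"] = out / "indicators.csv"
    df.to_csv(paths["csv"], index=False)
    paths["json"] = out / "indicators.json"
    paths["json"].write_text(json.dumps(rows, indent=1, default=str))
    manifest["bounce_fraction"] = bounce_fraction
    manifest["parse_errors"] = len(parsed.errors)
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths


def annual_report(
    indicator_sets: Sequence[IndicatorSet],
    registry: Registry,
    profiles: Optional[dict[str, SpeciesProfile]] = None,
    baseline: Optional[SpeciesBaseline] = None,
) -> pd.DataFrame:
    """Ranked per-publisher summary table for one window.

    Rank is by UIF (usage impact) descending; ties break by stored records
    r descending, then unit_id. UCI is filled where a species profile and
    baseline are supplied.
    """
    rows = []
    for ind in indicator_sets:
        unit = registry.unit(ind.unit_id)
        uci = None
        if profiles and baseline and ind.unit_id in profiles:
            uci = usage_crown_indicator(
                profiles[ind.unit_id], baseline, d_total=ind.d
            )
        rows.append(
            {
                "unit_id": ind.unit_id,
                "window": ind.window,
                "size_class": registry.size_class(unit).value,
                "N": ind.N,
                "n": ind.n,
                "r": ind.r,
                "s": ind.s,
                "d": ind.d,
                "UIF": ind.usage_impact,
                "IIF": ind.interest_impact,
                "UCI": uci,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["UIF", "r", "unit_id"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def format_annual_report(df: pd.DataFrame) -> str:
    """Human-readable, locale-independent rendering of the annual report."""
    return df.to_string(
        index=False, float_format=lambda x: f"{x:.2f}", na_rep="-"
    )
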