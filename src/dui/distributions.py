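"""Rank distributions and long-tail concentration summaries.

Stored records and usage over datasets, publishers or species follow the
familiar long-tail pattern: a few units hold most of the records while many
hold few. rank_distribution produces the descending rank table (with
cumulative shares) such spreadsheet-style analyses start from, and
tail_summary quantifies concentration with the top-k share and the Gini
coefficient. No power-law fit is attempted; the concentration summaries
deliberately stay model-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["RankTable", "TailSummary", "rank_distribution", "tail_summary"]

VALUE_KINDS = ("records", "searched", "downloaded")


@dataclass(frozen=True)
class RankTable:
    """Units sorted by a non-negative value, descending; 1-based ranks.

    Ties keep a stable order by unit_id so the table is reproducible and
    independent of input order.
    """

    table: pd.DataFrame  # columns: rank, unit_id, value, cumulative_share
    value_kind: str

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


class TailSummary(NamedTuple):
    top_k_share: Optional[float]
    gini: Optional[float]


def rank_distribution(
    units: Union[Mapping[str, float], Iterable[tuple[str, float]]],
    value_kind: str = "records",
) -> RankTable:
    """Rank units by value, descending, with cumulative shares.

    units is a mapping or iterable of (unit_id, value); ties are broken by
    unit_id. The cumulative_share column is NaN when all values are zero.
    """
    if value_kind not in VALUE_KINDS:
        raise ValidationError(f"value_kind must be one of {VALUE_KINDS}")
    pairs = list(units.items()) if isinstance(units, Mapping) else list(units)
    if not pairs:
        raise ValidationError("rank_distribution needs at least one unit")
    if any(v < 0 for _, v in pairs):
        raise ValidationError("values must be non-negative")
    df = pd.DataFrame(pairs, columns=["unit_id", "value"])
    df = df.sort_values(
        ["value", "unit_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    total = df["value"].sum()
    df["cumulative_share"] = (
        df["value"].cumsum() / total if total > 0 else np.nan
    )
    return RankTable(table=df, value_kind=value_kind)


def tail_summary(table: RankTable, k: int) -> TailSummary:
    """Top-k share and Gini coefficient of a rank table.

    top_k_share is the fraction of the total held by the k highest-ranked
    units. The Gini coefficient uses the standard sorted-sum formula
    G = Σ_i (2i - n - 1) x_(i) / (n Σ x) with x ascending. Both are None
    (undefined) when every value is zero.
    """
    n = len(table)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    values = table.table["value"].to_numpy(dtype=float)
    total = values.sum()
    if total == 0:
        return TailSummary(None, None)
    # table is descending; top-k are the first k rows
    top_k_share = values[:k].sum() / total
    x = np.sort(values)
    i = np.arange(1, n + 1)
    gini = float(((2 * i - n - 1) * x).sum() / (n * total))
    return TailSummary(float(top_k_share), gini)
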