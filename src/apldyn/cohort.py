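"""Cohort count-table arithmetic (demographics / outcome proportions)."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .params import load_fixture

__all__ = ["CountTable", "proportion", "summarize_counts", "table1_counts"]


@dataclass
class CountTable:
    """Labelled counts over a cohort of known size."""

    counts: dict[str, int]
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        for k, v in self.counts.items():
            if not (0 <= v <= self.denominator):
                raise ValueError(
                    f"count {k}={v} outside [0, {self.denominator}]"
                )


def proportion(count: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100·count/denominator, rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= count <= denominator):
        raise ValueError("count must lie in [0, denominator]")
    q = Decimal(1).scaleb(-decimals)
    pct = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def summarize_counts(table: CountTable, decimals: int = 1) -> pd.DataFrame:
    """Count table with an appended percentage column."""
    rows = [
        {
            "category": k,
            "count": v,
            "percentage": proportion(v, table.denominator, decimals),
        }
        for k, v in table.counts.items()
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percentage"])


def table1_counts(which: str = "counts") -> CountTable:
    """Packaged cohort counts (``"counts"`` or ``"trial_comparison_counts"``)."""
    d = load_fixture("table1_counts.json")
    return CountTable(counts=dict(d[which]), denominator=int(d["denominator"]))
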