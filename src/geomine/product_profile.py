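"""Alcohol titer summaries: totals, percentages and longer-chain fractions.

In-vivo fermentations report per-alcohol titers (mg/l) over replicates with a
limit of quantitation (LOQ, default 5 mg/l); an alcohol counts as quantified
only when every replicate is above the LOQ.  Summaries give the total titer
over quantified alcohols, integer percentages of that total, and the fraction
contributed by longer-chain alcohols (chain length >= a cutoff, default C5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_LOQ_MG_L = 5.0

ALCOHOL_CHAIN_LENGTH = {
    "ethanol": 2,
    "propanol": 3,
    "butanol": 4,
    "pentanol": 5,
    "hexanol": 6,
    "heptanol": 7,
    "octanol": 8,
}

__all__ = [
    "DEFAULT_LOQ_MG_L",
    "ALCOHOL_CHAIN_LENGTH",
    "TiterTable",
    "TiterSummary",
    "summarize_titers",
    "compare_profiles",
]


@dataclass(frozen=True)
class TiterTable:
    """Per-alcohol titers (mg/l) for one strain, with LOQ bookkeeping.

    ``replicates`` maps alcohol -> replicate titers; an alcohol is quantified
    iff every replicate is at or above ``loq``.  ``chain_length`` may extend
    or override the built-in alcohol naming.
    """

    strain: str
    replicates: dict[str, tuple[float, ...]]
    loq: float = DEFAULT_LOQ_MG_L
    chain_length: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.loq < 0:
            raise ValueError("limit of quantitation must be >= 0")
        reps = {a: tuple(float(x) for x in r) for a, r in self.replicates.items()}
        object.__setattr__(self, "replicates", reps)
        for a, r in reps.items():
            if not r:
                raise ValueError(f"alcohol {a!r} has no replicates")
            if any(x < 0 for x in r):
                raise ValueError(f"negative titer for {a!r}")
            self.chain_of(a)  # raises for unknown alcohols

    @classmethod
    def from_means(
        cls,
        strain: str,
        means: Mapping[str, float],
        loq: float = DEFAULT_LOQ_MG_L,
        chain_length: Mapping[str, int] | None = None,
    ) -> "TiterTable":
        """Single-value table, e.g. for published mean titers."""
        return cls(
            strain=strain,
            replicates={a: (float(v),) for a, v in means.items()},
            loq=loq,
            chain_length=dict(chain_length or {}),
        )

    def chain_of(self, alcohol: str) -> int:
        if alcohol in self.chain_length:
            return self.chain_length[alcohol]
        if alcohol in ALCOHOL_CHAIN_LENGTH:
            return ALCOHOL_CHAIN_LENGTH[alcohol]
        raise ValueError(f"unknown alcohol {alcohol!r}: supply chain_length")

    def is_quantified(self, alcohol: str) -> bool:
        return all(x >= self.loq for x in self.replicates[alcohol])

    @property
    def quantified_means(self) -> dict[str, float]:
        return {
            a: float(np.mean(r))
            for a, r in self.replicates.items()
            if self.is_quantified(a)
        }

    @property
    def below_loq(self) -> tuple[str, ...]:
        return tuple(a for a in self.replicates if not self.is_quantified(a))


@dataclass(frozen=True)
class TiterSummary:
    strain: str
    titers: dict[str, float]  # quantified alcohols only
    total: float
    longer_chain_total: float
    longer_chain_fraction: float
    percents: dict[str, int]  # integer percent of total, half away from zero
    fractions: dict[str, float]  # exact fractions, same denominators
    longer_chain_min: int
    loq: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_titers(table: TiterTable, longer_chain_min: int = 5) -> TiterSummary:
    """Totals, integer percentages and the longer-chain fraction of a profile.

    All denominators are the total over the strain's quantified alcohols.
    """
    titers = table.quantified_means
    if not titers:
        raise ValueError(f"strain {table.strain!r} has no quantified alcohols")
    total = sum(titers.values())
    longer = {a: v for a, v in titers.items() if table.chain_of(a) >= longer_chain_min}
    longer_total = sum(longer.values())
    fractions = {a: v / total for a, v in titers.items()}
    percents = {a: _round_half_away(100.0 * f) for a, f in fractions.items()}
    return TiterSummary(
        strain=table.strain,
        titers=titers,
        total=total,
        longer_chain_total=longer_total,
        longer_chain_fraction=longer_total / total,
        percents=percents,
        fractions=fractions,
        longer_chain_min=longer_chain_min,
        loq=table.loq,
    )


@dataclass(frozen=True)
class TiterFold:
    value: float
    lower_bound: bool = False


def compare_profiles(a: TiterTable, b: TiterTable) -> dict[str, TiterFold]:
    """Per-alcohol fold changes of a over b.

    Alcohols quantified in ``a`` but below the LOQ (or absent) in ``b`` give
    lower-bound folds computed at the LOQ; alcohols absent from both are
    omitted.  Raises when the two profiles share no alcohol at all.
    """
    a_q = a.quantified_means
    b_q = b.quantified_means
    considered = set(a_q) | set(b_q) | set(a.replicates) | set(b.replicates)
    if not considered:
        raise ValueError("profiles share no alcohols")
    folds: dict[str, TiterFold] = {}
    for alcohol in sorted(considered):
        if alcohol in a_q and alcohol in b_q:
            folds[alcohol] = TiterFold(value=a_q[alcohol] / b_q[alcohol])
        elif alcohol in a_q:
            folds[alcohol] = TiterFold(value=a_q[alcohol] / b.loq, lower_bound=True)
        # quantified only in b (or in neither): no informative fold for a/b
    if not folds:
        raise ValueError("no quantified alcohols to compare")
    return folds


def titers_to_frame(table: TiterTable) -> pd.DataFrame:
    """Long-format view: strain, alcohol, chain_length, replicate columns."""
    rows = []
    for alcohol, reps in table.replicates.items():
        row = {
            "strain": table.strain,
            "alcohol": alcohol,
            "chain_length": table.chain_of(alcohol),
            "quantified": table.is_quantified(alcohol),
        }
        row.update({f"rep{i + 1}": v for i, v in enumerate(reps)})
        rows.append(row)
    return pd.DataFrame(rows)
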