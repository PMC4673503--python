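"""Combinatorial active-site mutant libraries from design-simulation profiles.

A set of low-energy computational designs over a fixed panel of active-site
positions is collapsed into a per-position profile of observed (non-native)
amino acids.  The profile defines a screening library: every option as a
single mutant, plus all cross-product double mutants for pairs of design
positions lying within a proximity window in sequence.  Coverage statistics
describe how many colonies must be picked to sample the library, and the
screen filter applies an activity-over-wild-type threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignProfile",
    "MutantLibrary",
    "build_profile",
    "enumerate_library",
    "combinatorial_space",
    "coverage_probability",
    "screen_filter",
]

Variant = tuple[tuple[int, str], ...]  # ((position, new_residue), ...) sorted by position


@dataclass(frozen=True)
class DesignProfile:
    """Per-position sets of non-native residues observed among designs."""

    native: str
    positions: tuple[int, ...]
    options: dict[int, frozenset[str]]

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("design positions must be distinct")
        for p in self.positions:
            if not (1 <= p <= len(self.native)):
                raise ValueError(f"design position {p} outside native length {len(self.native)}")
            if self.native[p - 1] in self.options.get(p, frozenset()):
                raise ValueError(f"option set at position {p} contains the native residue")

    @property
    def n_options(self) -> int:
        return sum(len(self.options[p]) for p in self.positions)


@dataclass(frozen=True)
class MutantLibrary:
    """Enumerated list of substitution sets over a native scaffold."""

    native: str
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        seen = set()
        for var in self.variants:
            if not var:
                raise ValueError("empty variant in library")
            pos = [p for p, _ in var]
            if len(set(pos)) != len(pos):
                raise ValueError(f"variant {var} repeats a position")
            if var in seen:
                raise ValueError(f"duplicate variant {var}")
            seen.add(var)

    @property
    def theoretical_size(self) -> int:
        return len(self.variants)

    def mutant_sequence(self, variant: Variant) -> str:
        seq = list(self.native)
        for pos, aa in variant:
            seq[pos - 1] = aa
        return "".join(seq)

    def variant_name(self, variant: Variant) -> str:
        return "_".join(f"{self.native[p - 1]}{p}{aa}" for p, aa in variant)


def build_profile(
    designs: Sequence[str], native: str, positions: Sequence[int]
) -> DesignProfile:
    """Tally observed non-native residues per design position.

    Redundant (duplicate) design sequences are collapsed before tallying.
    All designs must have the native length.
    """
    if not designs:
        raise ValueError("need at least one design")
    positions = tuple(sorted(positions))
    for i, d in enumerate(designs):
        if len(d) != len(native):
            raise ValueError(
                f"design {i} length {len(d)} does not match native length {len(native)}"
            )
    unique = list(dict.fromkeys(designs))
    options: dict[int, frozenset[str]] = {}
    for p in positions:
        seen = {d[p - 1] for d in unique}
        options[p] = frozenset(seen - {native[p - 1]})
    return DesignProfile(native=native, positions=positions, options=options)


def enumerate_library(profile: DesignProfile, pairing_window: int = 5) -> MutantLibrary:
    """Enumerate the single + proximal-double mutant library for a profile.

    Every (position, residue) option yields a single mutant.  For every pair
    of design positions whose index difference is at most ``pairing_window``,
    every cross-product combination of the two option sets yields a double
    mutant.  Variants are deduplicated and sorted by (first position, first
    residue, second position, second residue).
    """
    if pairing_window < 0:
        raise ValueError(f"pairing_window must be >= 0, got {pairing_window}")
    variants: set[Variant] = set()
    for p in profile.positions:
        for aa in profile.options[p]:
            variants.add(((p, aa),))
    for i, p in enumerate(profile.positions):
        for q in profile.positions[i + 1 :]:
            if abs(q - p) <= pairing_window:
                for aa_p in profile.options[p]:
                    for aa_q in profile.options[q]:
                        variants.add(((p, aa_p), (q, aa_q)))

    def key(var: Variant):
        # (first position, first residue, second position, second residue);
        # singles sort before doubles sharing the same prefix
        flat: list = []
        for pos, aa in var:
            flat.extend((pos, aa))
        return flat

    ordered = tuple(sorted(variants, key=key))
    return MutantLibrary(native=profile.native, variants=ordered)


def combinatorial_space(n_positions: int, options_per_position: int) -> int:
    """Size of the full combinatorial sequence space, exact integer arithmetic."""
    if n_positions < 1 or options_per_position < 1:
        raise ValueError("n_positions and options_per_position must be >= 1")
    return options_per_position**n_positions


def coverage_probability(library_size: int, n_picked: int) -> float:
    """Expected per-variant coverage when picking colonies with replacement.

    Under uniform sampling with replacement of ``n_picked`` colonies from a
    library of ``library_size`` distinct variants, each variant is seen with
    probability 1 - (1 - 1/N)^n, which equals the expected covered fraction
    of the library.  At n = 3N this approaches 1 - e^-3 ~ 0.950 for large N.
    """
    if library_size < 1:
        raise ValueError(f"library_size must be >= 1, got {library_size}")
    if n_picked < 0:
        raise ValueError(f"n_picked must be >= 0, got {n_picked}")
    return float(1.0 - (1.0 - 1.0 / library_size) ** n_picked)


def coverage_probability_mc(
    library_size: int, n_picked: int, n_trials: int = 1000, seed: int | None = None
) -> float:
    """Monte-Carlo estimate of the expected covered library fraction."""
    rng = np.random.default_rng(seed)
    covered = np.empty(n_trials)
    for t in range(n_trials):
        picks = rng.integers(0, library_size, size=n_picked)
        covered[t] = np.unique(picks).size / library_size
    return float(covered.mean())


def screen_filter(
    activity_table: pd.DataFrame,
    wildtype_row: str | Mapping[str, float],
    min_fold: float = 1.25,
) -> dict[str, list[str]]:
    """Variants with activity >= ``min_fold`` x wild type on any substrate.

    ``activity_table`` is variants x substrates.  ``wildtype_row`` is either
    the index label of the wild-type row or an explicit substrate -> activity
    mapping.  Returns passing variants mapped to their qualifying substrates
    (threshold inclusive).
    """
    if isinstance(wildtype_row, str):
        if wildtype_row not in activity_table.index:
            raise ValueError(f"wild-type row {wildtype_row!r} not in table")
        wt = activity_table.loc[wildtype_row]
        table = activity_table.drop(index=wildtype_row)
    else:
        wt = pd.Series(dict(wildtype_row))
        table = activity_table
    missing = set(table.columns) - set(wt.index)
    if missing:
        raise ValueError(f"wild-type activity missing for substrates {sorted(missing)}")
    if (wt[list(table.columns)] <= 0).any():
        bad = [s for s in table.columns if wt[s] <= 0]
        raise ValueError(f"wild-type activity must be > 0, offending substrates: {bad}")

    passing: dict[str, list[str]] = {}
    for variant, row in table.iterrows():
        qualifying = [s for s in table.columns if row[s] >= min_fold * wt[s]]
        if qualifying:
            passing[str(variant)] = qualifying
    return passing
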