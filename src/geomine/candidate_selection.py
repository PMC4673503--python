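"""Docking-score reduction and diversity-aware candidate selection.

Each candidate enzyme arrives with a table of docked models (total protein
energy and protein-ligand interface energy per model, in Rosetta-energy-unit-
like scores; lower is better).  The table is reduced to a single interface
energy per candidate, candidates are ranked, and the final panel is chosen as
the k lowest-energy candidates plus k further candidates picked for sequence
diversity (greedy clustering of the remainder at an identity threshold,
then the lowest-energy cluster representatives).  Mutations introduced during
design simulations are reverted unless they improve the interface energy by
more than a stated margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_mining import IdentityMatrix, SequenceRecord, greedy_cluster

__all__ = [
    "Mutation",
    "GeoCandidate",
    "DockingScoreTable",
    "SelectionResult",
    "reduce_docking_scores",
    "select_candidates",
    "bar_heights",
    "revert_mutations",
]


@dataclass(frozen=True)
class Mutation:
    """A designed point mutation and its predicted interface-energy change.

    ``delta_interface_energy`` is the energy change introduced by the
    mutation; negative values are improvements.  ``improvement`` is the
    positive-is-better view of the same number.
    """

    position: int  # 1-based
    native: str
    designed: str
    delta_interface_energy: float

    @property
    def improvement(self) -> float:
        return -self.delta_interface_energy


@dataclass(frozen=True)
class GeoCandidate:
    """A candidate enzyme: sequence record plus externally computed scores."""

    record: SequenceRecord
    tm_score: float | None = None
    interface_energy: float | None = None
    designed_mutations: tuple[Mutation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "designed_mutations", tuple(self.designed_mutations))
        if self.interface_energy is not None and not math.isfinite(self.interface_energy):
            raise ValueError(f"candidate {self.record.id!r}: interface_energy not finite")
        for m in self.designed_mutations:
            if not (1 <= m.position <= len(self.record.sequence)):
                raise ValueError(
                    f"candidate {self.record.id!r}: mutation position {m.position} "
                    f"outside sequence length {len(self.record.sequence)}"
                )

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self.record.sequence

    @property
    def taxonomy_domain(self) -> str:
        return self.record.taxonomy_domain


@dataclass(frozen=True)
class DockingScoreTable:
    """Per-model docking scores for one candidate.

    ``rows`` is a DataFrame with columns ``model_idx``, ``total_energy``,
    ``interface_energy``.
    """

    candidate_id: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"model_idx", "total_energy", "interface_energy"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        if len(self.rows) < 1:
            raise ValueError(f"score table for {self.candidate_id!r} is empty")
        vals = self.rows[["total_energy", "interface_energy"]].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"score table for {self.candidate_id!r} has non-finite energies")


@dataclass(frozen=True)
class SelectionResult:
    energy_picks: tuple[str, ...]
    diversity_picks: tuple[str, ...]
    diversity_threshold: float

    def __post_init__(self) -> None:
        if set(self.energy_picks) & set(self.diversity_picks):
            raise ValueError("energy and diversity picks must be disjoint")

    @property
    def selected(self) -> tuple[str, ...]:
        return self.energy_picks + self.diversity_picks


def reduce_docking_scores(table: DockingScoreTable, n_keep: int = 100) -> float:
    """Two-stage reduction of a docking table to one interface energy.

    The ``n_keep`` rows of lowest total energy are retained (ties at the
    boundary broken by model index, ascending) and the minimum interface
    energy within that subset is returned.
    """
    if n_keep < 1:
        raise ValueError(f"n_keep must be >= 1, got {n_keep}")
    ordered = table.rows.sort_values(
        ["total_energy", "model_idx"], kind="mergesort"
    ).head(n_keep)
    return float(ordered["interface_energy"].min())


def select_candidates(
    candidates: Sequence[GeoCandidate],
    identity: IdentityMatrix,
    k_energy: int = 5,
    k_diverse: int = 5,
    diversity_threshold: float = 0.40,
) -> SelectionResult:
    """Pick ``k_energy`` lowest-energy candidates plus ``k_diverse`` diverse ones.

    The energy picks are simply the ``k_energy`` candidates of lowest
    interface energy (ties by id).  The remaining candidates are greedily
    clustered at ``diversity_threshold``; each cluster contributes its
    lowest-energy member, and the ``k_diverse`` lowest-energy of those
    cluster representatives become the diversity picks.
    """
    if any(c.interface_energy is None for c in candidates):
        missing = [c.id for c in candidates if c.interface_energy is None]
        raise ValueError(f"candidates missing interface_energy: {missing}")
    need = k_energy + k_diverse
    if len(candidates) < need:
        raise ValueError(
            f"need at least {need} candidates (k_energy + k_diverse), got {len(candidates)}"
        )
    by_energy = sorted(candidates, key=lambda c: (c.interface_energy, c.id))
    energy_picks = tuple(c.id for c in by_energy[:k_energy])

    remainder = [c for c in by_energy[k_energy:]]
    clusters = greedy_cluster(
        [c.record for c in remainder], diversity_threshold, identity=identity
    )
    by_id = {c.id: c for c in remainder}
    reps: list[GeoCandidate] = []
    for _, member_ids in clusters.clusters:
        best = min((by_id[m] for m in member_ids), key=lambda c: (c.interface_energy, c.id))
        reps.append(best)
    if len(reps) < k_diverse:
        raise ValueError(
            f"only {len(reps)} diversity-cluster representatives available, "
            f"need {k_diverse}"
        )
    reps.sort(key=lambda c: (c.interface_energy, c.id))
    diversity_picks = tuple(c.id for c in reps[:k_diverse])
    return SelectionResult(
        energy_picks=energy_picks,
        diversity_picks=diversity_picks,
        diversity_threshold=diversity_threshold,
    )


def bar_heights(energies: Sequence[float]) -> np.ndarray:
    """Linear bar heights in [0, 1], 1 for the lowest energy, 0 for the highest.

    h_i = (E_max - E_i) / (E_max - E_min); when all energies are equal every
    height is 1.0 (degenerate rule, keeping "relative to the lowest" intact).
    """
    e = np.asarray(list(energies), dtype=float)
    if e.size < 1:
        raise ValueError("need at least one energy")
    if not np.isfinite(e).all():
        raise ValueError("energies must be finite")
    emin, emax = e.min(), e.max()
    if emax == emin:
        return np.ones_like(e)
    return (emax - e) / (emax - emin)


def revert_mutations(
    candidate: GeoCandidate, improvement_threshold: float = 2.0
) -> tuple[str, tuple[Mutation, ...]]:
    """Revert designed mutations that do not clear the improvement margin.

    A mutation is kept iff its predicted interface-energy improvement is
    strictly greater than ``improvement_threshold`` (in the same energy
    units); all others revert to the native residue.  Returns the resulting
    sequence and the kept mutations.  The candidate's sequence is taken as
    the native scaffold.
    """
    seen: dict[int, Mutation] = {}
    for m in candidate.designed_mutations:
        if m.position in seen and seen[m.position].designed != m.designed:
            raise ValueError(
                f"conflicting mutations at position {m.position} of {candidate.id!r}"
            )
        seen[m.position] = m
    seq = list(candidate.sequence)
    kept = []
    for m in sorted(seen.values(), key=lambda m: m.position):
        if seq[m.position - 1] != m.native:
            raise ValueError(
                f"{candidate.id!r}: native residue mismatch at position {m.position} "
                f"({seq[m.position - 1]!r} != {m.native!r})"
            )
        if m.improvement > improvement_threshold:
            seq[m.position - 1] = m.designed
            kept.append(m)
    return "".join(seq), tuple(kept)
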