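"""Filtering and identity-structure analysis of a candidate homologue set.

A mined set of genomic enzyme orthologues (GEOs) arrives as protein sequences
with taxonomy labels and externally computed structure scores.  This module
provides the pre-selection stages of the mining pipeline: pairwise percent
identity, CD-HIT-style greedy identity clustering for deduplication, the
taxonomy / fold-similarity filters, and the identity-histogram mode used to
characterize the sequence diversity of the surviving set.

Identity convention
-------------------
Identity between two sequences is computed from a single optimal global
alignment (BLOSUM62, gap open 11, gap extend 1) as the number of identical
aligned residue pairs divided by the length of the *shorter* sequence — the
convention used by greedy deduplication tools.  ``X`` (unknown residue) never
counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}
TAXONOMY_DOMAINS = frozenset({"Bacteria", "Archaea", "Eukaryota", "Unknown"})

__all__ = [
    "AMINO_ACIDS",
    "SequenceRecord",
    "IdentityMatrix",
    "ClusterSet",
    "pairwise_identity",
    "identity_matrix",
    "greedy_cluster",
    "filter_records",
    "identity_mode",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with its taxonomy domain and free-text description."""

    id: str
    sequence: str
    taxonomy_domain: str = "Unknown"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of record {self.id!r} is empty")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-canonical residues {sorted(bad)}"
            )
        if self.taxonomy_domain not in TAXONOMY_DOMAINS:
            raise ValueError(
                f"record {self.id!r}: taxonomy_domain must be one of "
                f"{sorted(TAXONOMY_DOMAINS)}, got {self.taxonomy_domain!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric matrix of pairwise fractional identities, diagonal 1."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("identity matrix diagonal must be 1.0")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("identity values must lie in [0, 1]")

    def lookup(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class ClusterSet:
    """Greedy identity clustering result: (representative, members) partition."""

    threshold: float
    clusters: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def representatives(self) -> tuple[str, ...]:
        return tuple(rep for rep, _ in self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> tuple[str, ...]:
        return tuple(m for _, members in self.clusters for m in members)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def _aligned_matches(sa: str, sb: str) -> int:
    """Identical aligned residue pairs in one optimal global alignment."""
    alignment = _ALIGNER.align(sa, sb)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for x, y in zip(sa[a0:a1], sb[b0:b1]):
            if x == y and x != "X":
                matches += 1
    return matches


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fractional identity between two records in [0, 1].

    Symmetric; identical sequences give exactly 1.0.  The alignment is
    computed on the lexicographically ordered pair so that the result cannot
    depend on argument order even when several alignments are co-optimal.
    """
    sa, sb = a.sequence, b.sequence
    if sa == sb:
        return 1.0
    if sb < sa:
        sa, sb = sb, sa
    matches = _aligned_matches(sa, sb)
    return matches / min(len(sa), len(sb))


def identity_matrix(records: Sequence[SequenceRecord]) -> IdentityMatrix:
    """All-against-all identity matrix for a set of records."""
    if len(records) < 1:
        raise ValueError("need at least one record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")
    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pairwise_identity(records[i], records[j])
    return IdentityMatrix(ids=tuple(ids), values=values)


def _identity_lookup(
    records: Sequence[SequenceRecord],
    identity: IdentityMatrix | Callable[[SequenceRecord, SequenceRecord], float] | None,
) -> Callable[[SequenceRecord, SequenceRecord], float]:
    if identity is None:
        return pairwise_identity
    if isinstance(identity, IdentityMatrix):
        return lambda a, b: identity.lookup(a.id, b.id)
    return identity


def greedy_cluster(
    records: Sequence[SequenceRecord],
    threshold: float,
    identity: IdentityMatrix | Callable[[SequenceRecord, SequenceRecord], float] | None = None,
) -> ClusterSet:
    """Incremental greedy clustering at an identity threshold.

    Records are visited in length-descending order (ties by id, ascending);
    each record joins the first existing representative with identity >=
    ``threshold`` (inclusive), otherwise it founds a new cluster.
    Representatives are reported in founding order.

    Parameters
    ----------
    identity:
        Optional precomputed :class:`IdentityMatrix` (or a callable on record
        pairs); by default identities are computed on the fly.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    ident = _identity_lookup(records, identity)
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SequenceRecord] = []
    members: dict[str, list[str]] = {}
    for rec in ordered:
        for rep in reps:
            if ident(rec, rep) >= threshold:
                members[rep.id].append(rec.id)
                break
        else:
            reps.append(rec)
            members[rec.id] = [rec.id]
    clusters = tuple((rep.id, tuple(members[rep.id])) for rep in reps)
    return ClusterSet(threshold=threshold, clusters=clusters)


def filter_records(
    candidates: Sequence,
    tm_cutoff: float = 0.5,
    drop_eukaryotes: bool = True,
) -> tuple[list, list[tuple[str, str]]]:
    """Apply the fold-similarity and taxonomy filters.

    A candidate is kept iff its TM-score is strictly greater than
    ``tm_cutoff`` and (when ``drop_eukaryotes``) it is not of eukaryotic
    origin.  Returns ``(kept, rejection_log)`` where the log lists
    ``(id, reason)`` per dropped candidate; kept and dropped partition the
    input.
    """
    kept = []
    rejected: list[tuple[str, str]] = []
    for cand in candidates:
        tm = getattr(cand, "tm_score", None)
        if tm is None:
            raise ValueError(f"candidate {cand.id!r} is missing a tm_score")
        if not (0.0 <= tm <= 1.0):
            raise ValueError(f"candidate {cand.id!r}: tm_score {tm} outside [0, 1]")
        if drop_eukaryotes and cand.taxonomy_domain == "Eukaryota":
            rejected.append((cand.id, "eukaryote"))
        elif not tm > tm_cutoff:
            rejected.append((cand.id, f"tm_score {tm:g} <= cutoff {tm_cutoff:g}"))
        else:
            kept.append(cand)
    return kept, rejected


def identity_mode(matrix: IdentityMatrix, bin_width: float = 0.05) -> float:
    """Modal pairwise identity, as the midpoint of the most populated bin.

    The histogram is taken over the off-diagonal upper triangle with bins of
    ``bin_width`` covering [0, 1]; ties are broken toward the lower bin.
    """
    if not (0.0 < bin_width < 1.0):
        raise ValueError(f"bin_width must lie in (0, 1), got {bin_width}")
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("identity mode needs at least 2 sequences")
    iu = np.triu_indices(n, k=1)
    vals = matrix.values[iu]
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts, edges = np.histogram(vals, bins=edges)
    idx = int(np.argmax(counts))  # argmax returns the first (lower) max
    return float((edges[idx] + edges[idx + 1]) / 2.0)
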