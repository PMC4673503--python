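"""File formats: FASTA with key=value tags, score/mutation TSVs, .clstr text.

FASTA description lines may carry ``tax=<domain>`` and ``clade=<0|1>`` tags;
score tables are TSV with columns ``candidate_id model_idx total_energy
interface_energy``; cluster sets serialize both as CD-HIT-style ``.clstr``
text and as a flat TSV.
"""

from __future__ import annotations

import re
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .candidate_selection import DockingScoreTable, GeoCandidate, Mutation
from .sequence_mining import ClusterSet, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_score_table",
    "write_score_table",
    "read_docking_tables",
    "read_mutation_table",
    "write_clstr",
    "write_cluster_tsv",
]

_TAG_RE = re.compile(r"(\w+)=(\S+)")


def _parse_tags(description: str) -> dict[str, str]:
    return dict(_TAG_RE.findall(description))


def read_fasta(path) -> tuple[list[SequenceRecord], set[str]]:
    """Read records; returns (records, ids tagged ``clade=1``).

    Taxonomy is parsed from a ``tax=`` tag when present, else ``Unknown``.
    """
    records: list[SequenceRecord] = []
    clade_ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = _parse_tags(rec.description)
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                taxonomy_domain=tags.get("tax", "Unknown"),
                description=rec.description.split(None, 1)[1] if " " in rec.description else "",
            )
        )
        if tags.get("clade") == "1":
            clade_ids.add(rec.id)
    return records, clade_ids


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def write_score_table(candidates: Sequence[GeoCandidate], path) -> None:
    """Per-candidate summary scores as TSV (id, tm_score, interface_energy)."""
    df = pd.DataFrame(
        {
            "candidate_id": [c.id for c in candidates],
            "tm_score": [c.tm_score for c in candidates],
            "interface_energy": [c.interface_energy for c in candidates],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_docking_tables(path) -> list[DockingScoreTable]:
    """Read per-model docking scores grouped by candidate from one TSV."""
    df = pd.read_csv(path, sep="\t")
    tables = []
    for cid, grp in df.groupby("candidate_id", sort=False):
        tables.append(
            DockingScoreTable(
                candidate_id=str(cid),
                rows=grp[["model_idx", "total_energy", "interface_energy"]].reset_index(drop=True),
            )
        )
    return tables


def read_mutation_table(path) -> dict[str, list[Mutation]]:
    """TSV ``candidate_id position native designed delta_interface_energy``."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[Mutation]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["candidate_id"]), []).append(
            Mutation(
                position=int(row["position"]),
                native=str(row["native"]),
                designed=str(row["designed"]),
                delta_interface_energy=float(row["delta_interface_energy"]),
            )
        )
    return out


def write_clstr(clusters: ClusterSet, path, lengths: dict[str, int] | None = None) -> None:
    """CD-HIT-style ``.clstr`` text (representative marked with ``*``)."""
    lengths = lengths or {}
    with open(path, "w") as fh:
        for i, (rep, members) in enumerate(clusters.clusters):
            fh.write(f">Cluster {i}\n")
            for j, member in enumerate(members):
                length = lengths.get(member, 0)
                mark = "*" if member == rep else f"at {clusters.threshold * 100:.2f}%"
                fh.write(f"{j}\t{length}aa, >{member}... {mark}\n")


def write_cluster_tsv(clusters: ClusterSet, path) -> None:
    rows = [
        {"cluster": i, "representative": rep, "member": member}
        for i, (rep, members) in enumerate(clusters.clusters)
        for member in members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
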