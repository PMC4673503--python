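#!/usr/bin/env python
"""Run the pre-selection mining stages on the synthetic family.

Deduplicates at 90% identity, removes eukaryote-labelled sequences, applies
the TM-score > 0.5 fold filter, and characterizes the sequence diversity of
the survivors via the pairwise-identity histogram mode.  Writes the cluster
assignment and the filter log under results/mining/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from geomine import io
from geomine.sequence_mining import (
    filter_records,
    greedy_cluster,
    identity_matrix,
    identity_mode,
)
from geomine.synthetic_data import FamilySimSpec, ScoreSimSpec, simulate_family, simulate_scores

SEED = 20250925
OUT = Path(__file__).resolve().parent.parent / "results" / "mining"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records, clade = simulate_family(FamilySimSpec(n_sequences=80, root_length=200, seed=SEED))
    cands = simulate_scores(records, clade, ScoreSimSpec(seed=SEED))

    # stage 1: deduplicate at 90% identity (greedy, CD-HIT-style)
    clusters = greedy_cluster(records, 0.90)
    reps = set(clusters.representatives)
    io.write_clstr(clusters, OUT / "dedup90.clstr",
                   lengths={r.id: len(r.sequence) for r in records})
    io.write_cluster_tsv(clusters, OUT / "dedup90.tsv")
    print(f"90% dedup: {len(records)} -> {clusters.n_clusters} representatives")

    # stage 2: taxonomy + fold-similarity filters on the representatives
    rep_cands = [c for c in cands if c.id in reps]
    kept, rejected = filter_records(rep_cands, tm_cutoff=0.5, drop_eukaryotes=True)
    pd.DataFrame(rejected, columns=["candidate_id", "reason"]).to_csv(
        OUT / "rejections.tsv", sep="\t", index=False)
    n_euk = sum(1 for _, reason in rejected if reason == "eukaryote")
    print(f"filters: kept {len(kept)}/{len(rep_cands)} "
          f"({n_euk} eukaryote, {len(rejected) - n_euk} low TM-score)")

    # stage 3: identity structure of the surviving set
    surviving = [c.record for c in kept]
    matrix = identity_matrix(surviving)
    mode = identity_mode(matrix, bin_width=0.05)
    iu = np.triu_indices(len(surviving), k=1)
    print(f"identity: mode {mode:.3f}, mean {matrix.values[iu].mean():.3f} — "
          f"a deeply diverged single-fold family (published sets mode ~20%)")
    io.write_fasta(surviving, OUT / "survivors.fasta")
    counts, edges = np.histogram(matrix.values[iu], bins=np.arange(0, 1.05, 0.05))
    pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "pairs": counts}).to_csv(
        OUT / "identity_histogram.csv", index=False)


if __name__ == "__main__":
    main()
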