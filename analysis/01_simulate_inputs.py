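#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes a simulated homologue family (FASTA with taxonomy/clade tags), its
docking-style score table, a noisy initial-velocity curve, a design-set
FASTA and a replicate titer table under results/synthetic/, each with a JSON
truth sidecar.  Later scripts regenerate the same objects in memory from the
same seeds, so this script exists to let the inputs be inspected as files.
"""

import json
from pathlib import Path

import pandas as pd

from geomine import io
from geomine.product_profile import titers_to_frame
from geomine.sequence_mining import SequenceRecord
from geomine.synthetic_data import (
    FamilySimSpec,
    KineticsSimSpec,
    ScoreSimSpec,
    simulate_design_set,
    simulate_family,
    simulate_kinetics,
    simulate_scores,
    simulate_titers,
)

SEED = 20250925
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # family of 80 homologues, ~15% of which form the low-energy clade
    fam_spec = FamilySimSpec(n_sequences=80, root_length=200, seed=SEED)
    records, clade = simulate_family(fam_spec)
    io.write_fasta(records, OUT / "family.fasta")
    (OUT / "family.truth.json").write_text(json.dumps(
        {"clade_ids": sorted(clade), "n_sequences": len(records)}, indent=2))
    print(f"family: {len(records)} sequences, functional clade of {len(clade)}")

    cands = simulate_scores(records, clade, ScoreSimSpec(seed=SEED))
    io.write_score_table(cands, OUT / "scores.tsv")
    print(f"scores: wrote TM-scores and interface energies for {len(cands)} candidates")

    data, truth = simulate_kinetics(KineticsSimSpec(noise_sd=0.05, seed=SEED))
    pd.DataFrame({
        "S_mM": data.concentrations_mM,
        "v_M_per_s": data.velocities_M_per_s,
        "E0_M": data.enzyme_conc_M,
    }).to_csv(OUT / "kinetics.csv", index=False)
    truth["velocities_noiseless"] = list(truth["velocities_noiseless"])
    (OUT / "kinetics.truth.json").write_text(json.dumps(truth, indent=2))
    print(f"kinetics: {data.concentrations_mM.size}-point velocity curve "
          f"(true kcat {truth['kcat']} s^-1, KM {truth['KM_mM']} mM)")

    native = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG"
    positions = (5, 9, 12, 18, 24, 28, 33, 38, 44, 49)
    designs = simulate_design_set(50, positions, native, "VLIMFHGATYW", seed=SEED)
    io.write_fasta([SequenceRecord(id=f"design{i:03d}", sequence=d)
                    for i, d in enumerate(designs)], OUT / "designs.fasta")
    (OUT / "designs.truth.json").write_text(json.dumps(
        {"native": native, "positions": positions}, indent=2))
    print(f"designs: {len(designs)} sequences over {len(positions)} active-site positions")

    means = {"butanol": 19.0, "pentanol": 88.0, "hexanol": 160.0,
             "heptanol": 274.0, "octanol": 10.0}
    table, _ = simulate_titers(means, replicate_sd=8.0, n_reps=3, seed=SEED,
                               strain="synthetic_strain")
    titers_to_frame(table).to_csv(OUT / "titers.csv", index=False)
    print(f"titers: 3 replicates x {len(means)} alcohols (LOQ {table.loq} mg/l)")


if __name__ == "__main__":
    main()
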