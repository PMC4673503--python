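#!/usr/bin/env python
"""Kinetic model fits on synthetic velocity data with known truth.

Fits Michaelis-Menten curves to noiseless and noisy synthetic data (exact
and statistical parameter recovery), and the substrate-inhibition model to a
curve with a genuine Ki (model comparison against the plain fit).  Fit table
under results/kinetics/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from geomine.kinetics_analysis import fit_michaelis_menten, fit_substrate_inhibition
from geomine.synthetic_data import KineticsSimSpec, simulate_kinetics

SEED = 20250925
OUT = Path(__file__).resolve().parent.parent / "results" / "kinetics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    # noiseless: exact recovery
    data, truth = simulate_kinetics(KineticsSimSpec(noise_sd=0.0, seed=SEED))
    fit = fit_michaelis_menten(data)
    print(f"noiseless MM: kcat {fit.kcat:.4f} s^-1 (truth {truth['kcat']}), "
          f"KM {fit.km_mM:.4f} mM (truth {truth['KM_mM']}) — exact recovery")
    rows.append({"case": "noiseless_mm", "kcat": fit.kcat, "km_mM": fit.km_mM,
                 "ki_mM": None, "eff_M_per_s": fit.efficiency_M_per_s})

    # noisy: 200 replicates, distribution of recovered parameters
    kcats, kms = [], []
    for i in range(200):
        d, _ = simulate_kinetics(KineticsSimSpec(noise_sd=0.05, seed=SEED + i))
        f = fit_michaelis_menten(d)
        kcats.append(f.kcat)
        kms.append(f.km_mM)
    print(f"noisy MM (5% noise, 200 replicates): median kcat {np.median(kcats):.2f} "
          f"(truth 10.1), median KM {np.median(kms):.3f} (truth 0.58)")
    rows.append({"case": "noisy_mm_median", "kcat": float(np.median(kcats)),
                 "km_mM": float(np.median(kms)), "ki_mM": None,
                 "eff_M_per_s": float(np.median(kcats)) / (float(np.median(kms)) * 1e-3)})

    # substrate inhibition: velocity declines above ~2 mM
    data_si, truth_si = simulate_kinetics(KineticsSimSpec(
        true_Ki=2.0, noise_sd=0.02, seed=SEED))
    fsi = fit_substrate_inhibition(data_si)
    print(f"substrate inhibition: kcat {fsi.kcat:.2f}, KM {fsi.km_mM:.3f}, "
          f"Ki {fsi.ki_mM:.2f} mM (truth 2.0); "
          f"dAIC vs plain MM {fsi.diagnostics['delta_aic_vs_mm']:+.1f} "
          f"(negative favours inhibition)")
    rows.append({"case": "substrate_inhibition", "kcat": fsi.kcat,
                 "km_mM": fsi.km_mM, "ki_mM": fsi.ki_mM,
                 "eff_M_per_s": fsi.efficiency_M_per_s})

    pd.DataFrame(rows).to_csv(OUT / "fits.csv", index=False)


if __name__ == "__main__":
    main()
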