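"""Bundled published measurements used as analysis inputs.

Two small tables ship with the package:

* ``kinetic_constants.csv`` — published kcat (s^-1), KM (mM) and catalytic
  efficiency kcat/KM (M^-1 s^-1) with one-s.d. errors for eleven ketoacid
  decarboxylases (discovered GEOs, designed variants, the native reference
  KIVD and five naively selected family members) against four 2-ketoacid
  substrates (C3, C5, C8, isoC5).  Empty efficiency cells are below the
  0.2 M^-1 s^-1 detection limit (reported "n.d.") and load as left-censored.
* ``alcohol_titers.csv`` — published mean in-vivo alcohol titers (mg/l) for
  the two engineered production strains.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .kinetics_analysis import DETECTION_LIMIT, Censored
from .product_profile import DEFAULT_LOQ_MG_L, TiterTable

__all__ = [
    "load_kinetic_constants",
    "efficiency_map",
    "load_reported_titers",
]


def _data_path(name: str):
    return resources.files("geomine.data").joinpath(name)


def load_kinetic_constants() -> pd.DataFrame:
    """Published kinetic constants as a DataFrame of printed strings.

    Columns ``kcat``, ``km_mM``, ``eff`` (and their ``_sd`` companions) hold
    the printed decimal strings so that printed precision is preserved;
    missing/censored cells are empty strings.
    """
    with _data_path("kinetic_constants.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str).fillna("")
    return df


def efficiency_map(
    detection_limit: float = DETECTION_LIMIT,
) -> dict[str, dict[str, float | Censored]]:
    """Efficiencies keyed as [enzyme][substrate]; censored cells -> Censored."""
    df = load_kinetic_constants()
    out: dict[str, dict[str, float | Censored]] = {}
    for _, row in df.iterrows():
        eff = row["eff"]
        value: float | Censored
        value = Censored(limit=detection_limit) if eff == "" else float(eff)
        out.setdefault(row["enzyme"], {})[row["substrate"]] = value
    return out


def load_reported_titers(loq: float = DEFAULT_LOQ_MG_L) -> dict[str, TiterTable]:
    """Published per-strain alcohol titer tables keyed by strain."""
    with _data_path("alcohol_titers.csv").open() as fh:
        df = pd.read_csv(fh)
    tables: dict[str, TiterTable] = {}
    for strain, grp in df.groupby("strain"):
        tables[str(strain)] = TiterTable.from_means(
            strain=str(strain),
            means=dict(zip(grp["alcohol"], grp["titer_mg_l"])),
            loq=loq,
            chain_length=dict(zip(grp["alcohol"], grp["chain_length"])),
        )
    return tables
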