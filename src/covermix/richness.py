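"""Seeded and realized species/functional richness per observation.

Seeded richness comes from the treatment catalog; realized richness
counts the seeded species (or their distinct functional groups) actually
detected in the sampling quadrat with biomass above a presence
threshold.  The default threshold is zero: any positive biomass counts
as presence.
"""

from __future__ import annotations

import pandas as pd

from .catalog import Catalog
from .io import Dataset, PlotObservation

__all__ = ["realized_richness", "richness_table"]


def realized_richness(
    obs: PlotObservation,
    catalog: Catalog,
    level: str = "species",
    threshold: float = 0.0,
) -> int:
    """Count seeded species (or functional groups) present in a quadrat.

    Parameters
    ----------
    level
        ``"species"`` counts species; ``"functional"`` counts distinct
        functional groups among the present species.
    threshold
        Presence requires biomass strictly greater than this (g m^-2).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if level not in ("species", "functional"):
        raise ValueError(f"unknown richness level {level!r}")
    seeded = catalog.treatment(obs.treatment_id).species_codes
    present = [
        sp
        for sp, b in obs.cover_biomass_by_species.items()
        if sp in seeded and b > threshold
    ]
    if level == "species":
        return len(present)
    return len({catalog.functional_group(sp) for sp in present})


def richness_table(
    ds: Dataset, catalog: Catalog, threshold: float = 0.0
) -> pd.DataFrame:
    """One row per observation with seeded and realized richness.

    Columns: site, block, treatment, quadrat, seeded_sr, seeded_fr,
    realized_sr, realized_fr.
    """
    rows = []
    for o in ds.observations:
        sr, fr = catalog.seeded_richness(o.treatment_id)
        rows.append(
            {
                "site": o.site_id,
                "block": o.block,
                "treatment": o.treatment_id,
                "quadrat": o.quadrat_index,
                "seeded_sr": sr,
                "seeded_fr": fr,
                "realized_sr": realized_richness(o, catalog, "species", threshold),
                "realized_fr": realized_richness(o, catalog, "functional", threshold),
            }
        )
    return pd.DataFrame(rows)
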