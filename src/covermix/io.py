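"""Read, validate, and normalize plot/quadrat-level biomass tables.

Canonical schema is a long-format CSV: one row per
(site, block, treatment, quadrat, taxon) with a ``taxon_class`` column
("cover" or "weed") and a ``biomass`` column in g m^-2.  A user-supplied
column map adapts other headers to these logical names.  Rows with a
missing biomass value record an absent measurement, not a zero.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .catalog import Catalog

logger = logging.getLogger(__name__)

__all__ = [
    "PlotObservation",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "read_trial_csv",
    "write_trial_csv",
    "aggregate_quadrats",
    "total_cover_biomass",
    "total_weed_biomass",
    "reclassify_volunteers",
]

#: Logical column names of the canonical long format.
LOGICAL_COLUMNS = ("site", "block", "treatment", "quadrat", "taxon", "taxon_class", "biomass")

DEFAULT_QUADRAT_AREA = 0.18  # m^2


class SchemaError(ValueError):
    """Required logical columns could not be resolved in the input file."""


class ValidationError(ValueError):
    """An input row violates a data invariant (e.g. negative biomass)."""


@dataclass
class PlotObservation:
    """One quadrat's species-level cover and weed biomass (g m^-2)."""

    site_id: int
    block: int
    treatment_id: int
    quadrat_index: int = 1
    cover_biomass_by_species: dict[str, float] = field(default_factory=dict)
    weed_biomass_by_taxon: dict[str, float] = field(default_factory=dict)
    quadrat_area: float = DEFAULT_QUADRAT_AREA

    @property
    def key(self) -> tuple[int, int, int, int]:
        return (self.site_id, self.block, self.treatment_id, self.quadrat_index)

    @property
    def plot_key(self) -> tuple[int, int, int]:
        return (self.site_id, self.block, self.treatment_id)


@dataclass
class Dataset:
    """A collection of quadrat observations plus provenance."""

    observations: list[PlotObservation]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [o.key for o in self.observations]
        if len(keys) != len(set(keys)):
            seen: set[tuple] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate observation key {dup}")

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def for_site(self, site_id: int) -> list[PlotObservation]:
        return [o for o in self.observations if o.site_id == site_id]

    @property
    def site_ids(self) -> list[int]:
        return sorted({o.site_id for o in self.observations})

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame in the canonical schema."""
        rows = []
        for o in self.observations:
            base = {
                "site": o.site_id,
                "block": o.block,
                "treatment": o.treatment_id,
                "quadrat": o.quadrat_index,
                "quadrat_area": o.quadrat_area,
            }
            if not o.cover_biomass_by_species and not o.weed_biomass_by_taxon:
                rows.append({**base, "taxon": "", "taxon_class": "none", "biomass": 0.0})
            for sp, b in sorted(o.cover_biomass_by_species.items()):
                rows.append({**base, "taxon": sp, "taxon_class": "cover", "biomass": b})
            for tx, b in sorted(o.weed_biomass_by_taxon.items()):
                rows.append({**base, "taxon": tx, "taxon_class": "weed", "biomass": b})
        return pd.DataFrame(rows)


def total_cover_biomass(obs: PlotObservation) -> float:
    """Total cover crop biomass (g m^-2) in a quadrat: sum over species."""
    return float(sum(obs.cover_biomass_by_species.values()))


def total_weed_biomass(obs: PlotObservation) -> float:
    """Total weed biomass (g m^-2) in a quadrat: sum over weed taxa."""
    return float(sum(obs.weed_biomass_by_taxon.values()))


def _load_column_map(column_map: dict | str | Path | None) -> dict[str, str]:
    if column_map is None:
        return {}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh) or {}
    return dict(column_map)


def read_trial_csv(
    path: str | Path,
    column_map: dict | str | Path | None = None,
) -> Dataset:
    """Read a long-format trial CSV into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with one row per (site, block, treatment, quadrat, taxon).
    column_map
        Optional mapping (dict or YAML file) from logical column names
        (``site``, ``block``, ``treatment``, ``quadrat``, ``taxon``,
        ``taxon_class``, ``biomass``, ``quadrat_area``) to the actual
        headers in the file.  ``quadrat`` defaults to 1 and
        ``quadrat_area`` to 0.18 m^2 when no column resolves.
    """
    cmap = _load_column_map(column_map)
    df = pd.read_csv(path)

    resolved: dict[str, str] = {}
    missing = []
    for logical in LOGICAL_COLUMNS:
        actual = cmap.get(logical, logical)
        if actual in df.columns:
            resolved[logical] = actual
        elif logical in ("quadrat",):
            continue  # optional, defaults to 1
        else:
            missing.append(logical)
    if missing:
        raise SchemaError(
            f"cannot resolve required logical columns {missing} in {path}; "
            f"available columns: {list(df.columns)}"
        )
    area_col = cmap.get("quadrat_area", "quadrat_area")

    obs_map: dict[tuple[int, int, int, int], PlotObservation] = {}
    n_missing = 0
    for idx, row in df.iterrows():
        biomass = row[resolved["biomass"]]
        taxon_class = str(row[resolved["taxon_class"]]).strip().lower()
        key = (
            int(row[resolved["site"]]),
            int(row[resolved["block"]]),
            int(row[resolved["treatment"]]),
            int(row[resolved["quadrat"]]) if "quadrat" in resolved else 1,
        )
        if key not in obs_map:
            area = (
                float(row[area_col])
                if area_col in df.columns and pd.notna(row[area_col])
                else DEFAULT_QUADRAT_AREA
            )
            obs_map[key] = PlotObservation(*key, quadrat_area=area)
        if pd.isna(biomass):
            n_missing += 1  # absent measurement, not zero
            continue
        biomass = float(biomass)
        if biomass < 0:
            raise ValidationError(f"negative biomass {biomass} at row {idx} of {path}")
        taxon = str(row[resolved["taxon"]]).strip()
        o = obs_map[key]
        if taxon_class == "cover":
            o.cover_biomass_by_species[taxon] = o.cover_biomass_by_species.get(taxon, 0.0) + biomass
        elif taxon_class == "weed":
            o.weed_biomass_by_taxon[taxon] = o.weed_biomass_by_taxon.get(taxon, 0.0) + biomass
        elif taxon_class in ("none", "nan", ""):
            continue  # placeholder row for an empty plot
        else:
            raise ValidationError(
                f"unknown taxon_class {taxon_class!r} at row {idx} of {path}"
            )
    if n_missing:
        logger.info("read_trial_csv: %d rows with missing biomass recorded as absent", n_missing)
    return Dataset(list(obs_map.values()), provenance=str(path))


def write_trial_csv(ds: Dataset, path: str | Path) -> None:
    """Write a dataset in the canonical long format (round-trips with read)."""
    ds.to_frame().to_csv(path, index=False)


def aggregate_quadrats(ds: Dataset) -> Dataset:
    """Average multi-quadrat plots to one observation per (site, block, treatment).

    Species-wise and taxon-wise mean biomass across the plot's quadrats
    replaces the individual quadrats; single-quadrat plots pass through
    unchanged.  All downstream analyses operate on the aggregated plots.
    """
    groups: dict[tuple[int, int, int], list[PlotObservation]] = {}
    for o in ds.observations:
        groups.setdefault(o.plot_key, []).append(o)

    out = []
    for (site, block, trt), quads in groups.items():
        if len(quads) == 1:
            o = quads[0]
            if o.quadrat_index != 1:
                o = replace(o, quadrat_index=1)
            out.append(o)
            continue
        n = len(quads)
        cover: dict[str, float] = {}
        weed: dict[str, float] = {}
        for q in quads:
            for sp, b in q.cover_biomass_by_species.items():
                cover[sp] = cover.get(sp, 0.0) + b / n
            for tx, b in q.weed_biomass_by_taxon.items():
                weed[tx] = weed.get(tx, 0.0) + b / n
        out.append(
            PlotObservation(site, block, trt, 1, cover, weed, quads[0].quadrat_area)
        )
    return Dataset(out, provenance=ds.provenance + "|quadrats-aggregated")


def reclassify_volunteers(ds: Dataset, catalog: Catalog) -> Dataset:
    """Move cover species not in a treatment's seeded set to the weed map.

    A species growing in a plot where it was never seeded is an invader,
    so it counts toward weed biomass rather than cover biomass.
    """
    out = []
    n_moved = 0
    for o in ds.observations:
        seeded = catalog.treatment(o.treatment_id).species_codes
        volunteers = {sp for sp in o.cover_biomass_by_species if sp not in seeded}
        if not volunteers:
            out.append(o)
            continue
        cover = {sp: b for sp, b in o.cover_biomass_by_species.items() if sp not in volunteers}
        weed = dict(o.weed_biomass_by_taxon)
        for sp in volunteers:
            weed[f"volunteer:{sp}"] = weed.get(f"volunteer:{sp}", 0.0) + o.cover_biomass_by_species[sp]
            n_moved += 1
        out.append(replace(o, cover_biomass_by_species=cover, weed_biomass_by_taxon=weed))
    if n_moved:
        logger.info("reclassify_volunteers: moved %d species records to weeds", n_moved)
    return Dataset(out, provenance=ds.provenance)


def config_hash(obj) -> str:
    """Short stable hash used as provenance for synthetic datasets."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
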