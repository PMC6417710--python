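"""Experimental design catalog: species, functional groups, treatments, sites.

The trial uses 18 cover crop species, three from each of six functional
groups (cool/warm season x grass/legume/brassica-or-broadleaf), arranged
into 40 treatments: a no-cover control, 18 pure stands, and mixtures at
intermediate levels of species and functional richness, up to an
18-species mixture.  Mixtures follow a substitutive design: each species
is seeded at its pure-stand rate divided by the mixture's species
richness.  Eleven sites hosted the trial as a randomized complete block
design with four blocks (three at site 11).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SpeciesInfo",
    "TreatmentDefinition",
    "SiteInfo",
    "Catalog",
    "build_catalog",
    "mixture_seeding_rate",
]

#: Functional group codes: Cool/Warm season Grass, Legume, Brassica/Broadleaf.
FUNCTIONAL_GROUPS = ("CG", "CL", "CB", "WG", "WL", "WB")


@dataclass(frozen=True)
class SpeciesInfo:
    """One cover crop species and its pure-stand seeding rate.

    ``rate_2014`` carries the revised rate for species whose seeding rate
    changed in the trial's second year (the three cool-season brassicas,
    1.7 -> 1.1 g m^-2); ``None`` means the rate was unchanged.
    """

    code: str
    common_name: str
    functional_group: str
    pure_stand_rate: float  # g m^-2
    rate_2014: float | None = None

    def rate_for_year(self, year: int) -> float:
        if year >= 2014 and self.rate_2014 is not None:
            return self.rate_2014
        return self.pure_stand_rate


@dataclass(frozen=True)
class TreatmentDefinition:
    """Seeded composition of one treatment."""

    id: int
    species_codes: frozenset[str]
    season_class: str  # control | cool | warm | all
    name: str = ""

    @property
    def seeded_species_richness(self) -> int:
        return len(self.species_codes)

    def seeded_functional_richness(self, species_by_code: dict[str, SpeciesInfo]) -> int:
        return len({species_by_code[c].functional_group for c in self.species_codes})


@dataclass(frozen=True)
class SiteInfo:
    """Constants for one trial site."""

    site_id: int
    n_blocks: int
    year: int
    n_quadrats_per_plot: int
    sampled: bool
    weed_sampled: bool = False

    @property
    def treatment_ids(self) -> tuple[int, ...]:
        """Treatments present: 1-20 at 2013 sites, 1-40 at 2014 sites."""
        upper = 40 if self.year == 2014 else 20
        return tuple(range(1, upper + 1))


# ---------------------------------------------------------------------------
# Static design data

_SPECIES_ROWS = [
    # code, common name, group, rate (g m^-2), 2014 revision
    ("BAR", "barley", "CG", 16.8, None),
    ("OAT", "oat", "CG", 16.8, None),
    ("WHT", "wheat", "CG", 16.8, None),
    ("PEA", "Austrian winter pea", "CL", 11.2, None),
    ("RED", "red clover", "CL", 1.7, None),
    ("YEL", "yellow sweetclover", "CL", 1.7, None),
    ("RAD", "radish", "CB", 1.7, 1.1),
    ("RAPE", "rapeseed", "CB", 1.7, 1.1),
    ("TURN", "turnip", "CB", 1.7, 1.1),
    ("PROSO", "proso millet", "WG", 2.8, None),
    ("SORG", "sorghum sudangrass", "WG", 5.6, None),
    ("TEFF", "teff", "WG", 0.6, None),
    ("CHICK", "chickpea", "WL", 16.8, None),
    ("COW", "cowpea", "WL", 11.2, None),
    ("SUNN", "sunn hemp", "WL", 5.6, None),
    ("BUCK", "buckwheat", "WB", 11.2, None),
    ("SAFF", "safflower", "WB", 2.8, None),
    ("SUNF", "sunflower", "WB", 0.6, None),
]

_COOL9 = ("BAR", "OAT", "WHT", "PEA", "RED", "YEL", "RAD", "RAPE", "TURN")
_WARM9 = ("PROSO", "SORG", "TEFF", "CHICK", "COW", "SUNN", "BUCK", "SAFF", "SUNF")

_TREATMENT_ROWS: list[tuple[int, tuple[str, ...], str, str]] = [
    (1, (), "control", "no cover"),
    (2, ("BAR",), "cool", "barley"),
    (3, ("OAT",), "cool", "oat"),
    (4, ("WHT",), "cool", "wheat"),
    (5, ("PEA",), "cool", "Austrian winter pea"),
    (6, ("RED",), "cool", "red clover"),
    (7, ("YEL",), "cool", "yellow sweetclover"),
    (8, ("RAD",), "cool", "radish"),
    (9, ("RAPE",), "cool", "rapeseed"),
    (10, ("TURN",), "cool", "turnip"),
    (11, ("BAR", "OAT", "WHT"), "cool", "cool-season grasses"),
    (12, ("PEA", "RED", "YEL"), "cool", "cool-season legumes"),
    (13, ("RAD", "RAPE", "TURN"), "cool", "cool-season brassicas"),
    (14, ("BAR", "OAT", "WHT", "PEA", "RED", "YEL"), "cool", "grasses + legumes"),
    (15, ("BAR", "OAT", "WHT", "RAD", "RAPE", "TURN"), "cool", "grasses + brassicas"),
    (16, ("PEA", "RED", "YEL", "RAD", "RAPE", "TURN"), "cool", "legumes + brassicas"),
    (17, _COOL9, "cool", "all 9 cool-season species"),
    (18, ("BAR", "PEA", "RAD"), "cool", "BAR + PEA + RAD"),
    (19, ("OAT", "RED", "RAPE"), "cool", "OAT + RED + RAPE"),
    (20, ("WHT", "YEL", "TURN"), "cool", "WHT + YEL + TURN"),
    (21, ("PROSO",), "warm", "proso millet"),
    (22, ("SORG",), "warm", "sorghum sudangrass"),
    (23, ("TEFF",), "warm", "teff"),
    (24, ("CHICK",), "warm", "chickpea"),
    (25, ("COW",), "warm", "cowpea"),
    (26, ("SUNN",), "warm", "sunn hemp"),
    (27, ("BUCK",), "warm", "buckwheat"),
    (28, ("SAFF",), "warm", "safflower"),
    (29, ("SUNF",), "warm", "sunflower"),
    (30, ("PROSO", "SORG", "TEFF"), "warm", "warm-season grasses"),
    (31, ("CHICK", "COW", "SUNN"), "warm", "warm-season legumes"),
    (32, ("BUCK", "SAFF", "SUNF"), "warm", "warm-season broadleaves"),
    (33, ("PROSO", "SORG", "TEFF", "CHICK", "COW", "SUNN"), "warm", "WG + WL"),
    (34, ("PROSO", "SORG", "TEFF", "BUCK", "SAFF", "SUNF"), "warm", "WG + WB"),
    (35, ("CHICK", "COW", "SUNN", "BUCK", "SAFF", "SUNF"), "warm", "WL + WB"),
    (36, _WARM9, "warm", "all 9 warm-season species"),
    (37, ("PROSO", "CHICK", "BUCK"), "warm", "PROSO + CHICK + BUCK"),
    (38, ("SORG", "COW", "SAFF"), "warm", "SORG + COW + SAFF"),
    (39, ("TEFF", "SUNN", "SUNF"), "warm", "TEFF + SUNN + SUNF"),
    (40, _COOL9 + _WARM9, "all", "all 18 species"),
]

# Sites 1-9 seeded in 2013, 10-11 in 2014; biomass sampled at 3,4,5,7,8,10,11;
# weed biomass sampled only where weed growth was sufficient (3, 10, 11).
_SITE_ROWS = [
    # site, blocks, year, quadrats/plot, sampled, weed_sampled
    (1, 4, 2013, 1, False, False),
    (2, 4, 2013, 1, False, False),
    (3, 4, 2013, 2, True, True),
    (4, 4, 2013, 1, True, False),
    (5, 4, 2013, 1, True, False),
    (6, 4, 2013, 1, False, False),
    (7, 4, 2013, 1, True, False),
    (8, 4, 2013, 1, True, False),
    (9, 4, 2013, 1, False, False),
    (10, 4, 2014, 1, True, True),
    (11, 3, 2014, 1, True, True),
]


@dataclass(frozen=True)
class Catalog:
    """Queryable container for the full experimental design."""

    species: tuple[SpeciesInfo, ...]
    treatments: tuple[TreatmentDefinition, ...]
    sites: tuple[SiteInfo, ...]
    species_by_code: dict[str, SpeciesInfo] = field(default_factory=dict, repr=False)

    def treatment(self, treatment_id: int) -> TreatmentDefinition:
        try:
            return self.treatments[treatment_id - 1]
        except IndexError:
            raise KeyError(f"unknown treatment id {treatment_id}") from None

    def site(self, site_id: int) -> SiteInfo:
        try:
            return self.sites[site_id - 1]
        except IndexError:
            raise KeyError(f"unknown site id {site_id}") from None

    def functional_group(self, code: str) -> str:
        return self.species_by_code[code].functional_group

    def seeded_richness(self, treatment_id: int) -> tuple[int, int]:
        """(species richness, functional richness) of a treatment's seed mix."""
        t = self.treatment(treatment_id)
        return t.seeded_species_richness, t.seeded_functional_richness(self.species_by_code)

    @property
    def sampled_sites(self) -> tuple[SiteInfo, ...]:
        return tuple(s for s in self.sites if s.sampled)

    def species_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "code": s.code,
                    "common_name": s.common_name,
                    "functional_group": s.functional_group,
                    "pure_stand_rate": s.pure_stand_rate,
                    "rate_2014": s.rate_for_year(2014),
                }
                for s in self.species
            ]
        )

    def treatment_table(self) -> pd.DataFrame:
        """Long table: one row per (treatment, seeded species)."""
        rows = []
        for t in self.treatments:
            sr, fr = self.seeded_richness(t.id)
            if not t.species_codes:
                rows.append(
                    {"treatment": t.id, "species": None, "seeded_sr": 0, "seeded_fr": 0,
                     "season_class": t.season_class}
                )
            for code in sorted(t.species_codes):
                rows.append(
                    {"treatment": t.id, "species": code, "seeded_sr": sr, "seeded_fr": fr,
                     "season_class": t.season_class}
                )
        return pd.DataFrame(rows)


def build_catalog() -> Catalog:
    """Build the static design catalog: 18 species, 40 treatments, 11 sites."""
    species = tuple(SpeciesInfo(*row) for row in _SPECIES_ROWS)
    by_code = {s.code: s for s in species}
    treatments = tuple(
        TreatmentDefinition(tid, frozenset(codes), season, name)
        for tid, codes, season, name in _TREATMENT_ROWS
    )
    sites = tuple(SiteInfo(*row) for row in _SITE_ROWS)
    return Catalog(species, treatments, sites, by_code)


def mixture_seeding_rate(
    catalog: Catalog, treatment: TreatmentDefinition | int, species_code: str, year: int
) -> float:
    """Seeding rate (g m^-2) of one species within a treatment.

    Substitutive design: the pure-stand rate for that year divided by the
    mixture's seeded species richness.
    """
    if isinstance(treatment, int):
        treatment = catalog.treatment(treatment)
    if species_code not in treatment.species_codes:
        raise ValueError(
            f"species {species_code!r} is not seeded in treatment {treatment.id}"
        )
    sp = catalog.species_by_code[species_code]
    return sp.rate_for_year(year) / treatment.seeded_species_richness
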