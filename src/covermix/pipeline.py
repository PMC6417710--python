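"""End-to-end orchestration: run every analysis stage and emit tables.

``run_all`` takes either a trial CSV or a synthetic configuration and
writes the effect-size summary, the per-site invasibility table, the
stability regression table, the richness table, and a machine-readable
JSON bundle of all statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io, richness, simulate, stability
from .catalog import build_catalog
from .invasibility import fit_site_models
from .productivity import DiversityEffects, treatment_site_means

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source plus analysis flags."""

    input_csv: str | Path | None = None
    synthetic: simulate.SyntheticConfig | None = None
    column_map: str | Path | dict | None = None
    outdir: str | Path = "covermix_out"
    invasibility_richness: str = "realized"
    stability_richness: str = "seeded"
    presence_threshold: float = 0.0
    reclassify_volunteers: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_csv or synthetic config")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and write all output tables.

    Returns the statistics bundle that is also written to
    ``results.json`` in the output directory.
    """
    catalog = build_catalog()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        ds, truth = simulate.generate(config.synthetic, catalog)
        io.write_trial_csv(ds, outdir / "trial.csv")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(
                {
                    "expected_biomass": {
                        f"{s}:{t}": v for (s, t), v in truth.expected_biomass.items()
                    },
                    "beta1_true": truth.beta1_true,
                    "expected_effect_sizes": truth.expected_effect_sizes,
                },
                fh, indent=2, sort_keys=True, default=_jsonable,
            )
    else:
        ds = io.read_trial_csv(config.input_csv, config.column_map)
    if config.reclassify_volunteers:
        ds = io.reclassify_volunteers(ds, catalog)
    ds = io.aggregate_quadrats(ds)

    results: dict = {"provenance": ds.provenance}

    # productivity effect sizes
    eff = DiversityEffects(ds, catalog).fit()
    eff.summary().to_csv(outdir / "effects_summary.csv", index=False)
    eff.estimates_frame().to_csv(outdir / "effects_estimates.csv", index=False)
    treatment_site_means(ds, catalog).to_csv(outdir / "treatment_means.csv", index=False)
    results["effect_sizes"] = {
        name: s.as_dict() for name, s in eff.summaries.items()
    }

    # realized vs seeded richness
    rich = richness.richness_table(ds, catalog, config.presence_threshold)
    rich.to_csv(outdir / "richness.csv", index=False)

    # invasibility (sites with weed data only)
    inv = fit_site_models(
        ds, catalog, richness=config.invasibility_richness,
        threshold=config.presence_threshold,
    )
    inv.to_csv(outdir / "invasibility.csv", index=False)
    results["invasibility"] = inv.to_dict(orient="records")

    # stability
    records = stability.treatment_site_summary(ds, catalog, config.presence_threshold)
    records.to_csv(outdir / "stability_records.csv", index=False)
    stab_rows = []
    for interaction in (None, "SR", "FR"):
        fit = stability.StabilityModel(
            records, interaction=interaction, richness=config.stability_richness
        ).fit()
        stab_rows.append(fit.summary())
    import pandas as pd

    stab_table = pd.concat(stab_rows, ignore_index=True)
    stab_table.to_csv(outdir / "stability_fits.csv", index=False)
    results["stability"] = stab_table.to_dict(orient="records")
    try:
        results["cv_diagnostics"] = stability.cv_diagnostics(records).to_dict(orient="records")
    except ValueError as exc:
        logger.info("cv diagnostics unavailable: %s", exc)
        results["cv_diagnostics"] = None

    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_jsonable)
    logger.info("pipeline complete; outputs in %s", outdir)
    return results
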