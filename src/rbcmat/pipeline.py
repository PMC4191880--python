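"""End-to-end analysis pipeline over the packaged fixtures.

Runs cohort statistics → rate estimation → loss budgets → geometric
constraints → dry-mass simulations with a single :class:`RunConfig`,
writing CSV tables, feasibility verdicts, and simulation clouds to the
configured output directory, plus a machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import budget, drymass, geometry, io, population, rates, synthetic
from .constants import RunConfig

log = logging.getLogger("rbcmat")

#: the three published steady-state vesicle concentrations (vesicles/µL)
#: and the RBC concentration (cells/µL) they were measured against
VESICLE_CONCENTRATIONS = (30199.0, 2100.0, 169.0)
RBC_CONCENTRATION = 4.8e6


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute every stage on the packaged fixtures; returns the summary."""
    config = config or RunConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline config: %s", config)
    summary: dict = {"config": vars(config).copy()}

    stage = "population_stats"
    try:
        subjects = io.load_cohort()
        report = population.maturation_report(subjects)
        report.to_csv(outdir / "maturation_deltas.csv", index=False)
        summary["maturation"] = {
            r["quantity"]: {
                "mean_change": r["mean_change"],
                "ci": [r["ci_low"], r["ci_high"]],
                "pct_change": r["pct_change"],
            }
            for _, r in report.iterrows()
        }
        dv = summary["maturation"]["volume"]["mean_change"]
        dh = summary["maturation"]["hb"]["mean_change"]

        stage = "rate_estimation"
        f_values = [
            rates.steady_state_rate(v, RBC_CONCENTRATION, config.alpha_per_day)
            for v in VESICLE_CONCENTRATIONS
        ]
        geo_f = rates.geometric_rate_bound(
            130.0, radius_nm=83.5, lifespan=config.lifespan_days
        )
        summary["rates"] = {
            "steady_state_f": f_values,
            "geometric_bound_f": geo_f,
        }
        log.info("steady-state rates: %s; geometric bound %.2f", f_values, geo_f)

        stage = "loss_budget"
        table3 = budget.fraction_lost_table(
            subjects, [4.0, 10.0], radius_nm=100.0, mean_age=config.mean_age_days
        )
        table3.to_csv(outdir / "fraction_lost.csv")
        mean_conc = float(np.mean([s.total_conc for s in subjects]))
        verdicts = budget.feasibility_report(
            {"volume": dv, "hb": dh, "area": 23.3},
            mean_age=config.mean_age_days,
            cell_conc_gdl=mean_conc,
        )
        summary["budget"] = {
            "fraction_lost": table3.reset_index().to_dict(orient="records"),
            "required_radius_nm": budget.required_radius(
                "volume", dv, max(f_values), config.mean_age_days
            ),
            "feasibility": {
                q: {"feasible": v.feasible, "max_predicted": v.max_predicted}
                for q, v in verdicts.items()
            },
        }

        stage = "geometry_constraints"
        losses = io.load_loss_table()
        per_subject, mean_err = geometry.sv_consistency_error(
            losses["area_pct"], losses["volume_pct"]
        )
        cell = geometry.CellGeometry(volume=110.0, area=187.0)
        verdict = geometry.sole_mechanism_test(cell, vesicle_radius_nm=100.0)
        summary["geometry"] = {
            "sv_consistency_pct_points": list(per_subject),
            "sv_consistency_mean": mean_err,
            "sole_mechanism_feasible": verdict.feasible,
            "sv_ratio_cell_over_vesicle": 1.0 / verdict.ratio,
        }

        stage = "drymass_dynamics"
        rng_seed = config.seed
        retic = synthetic.gen_advia_population(
            synthetic.PopulationSpec(
                n_cells=2000,
                mean_volume=synthetic.RETIC_MEAN_VOLUME_FL,
                mean_hb=synthetic.RETIC_MEAN_HB_PG,
                label="reticulocyte",
            ),
            seed=rng_seed,
        )
        ref = synthetic.gen_volume_area_reference(4000, seed=rng_seed + 1)
        area0 = drymass.volume_match_area(
            retic["volume_fl"].to_numpy(),
            ref["volume_fl"].to_numpy(),
            ref["area_um2"].to_numpy(),
        )
        sampler = synthetic.radius_sampler(synthetic.RadiusDistributionSpec())
        constants = config.constants()
        m1 = drymass.simulate_model1(
            retic["hb_pg"].to_numpy(),
            area0,
            retic["conc_gdl"].to_numpy(),
            target_hb_loss=dh,
            radius_sampler=sampler,
            mean_age=config.mean_age_days,
            seed=rng_seed + 2,
            constants=constants,
        )
        m2 = drymass.simulate_model2(
            retic["hb_pg"].to_numpy(),
            area0,
            target_hb_loss=dh,
            radius_sampler=sampler,
            seed=rng_seed + 3,
            constants=constants,
        )
        m1.cloud_frame().to_csv(outdir / "model1_cloud.csv", index=False)
        m2.cloud_frame().to_csv(outdir / "model2_cloud.csv", index=False)
        summary["drymass"] = {
            "model1_implied_n_mean": float(m1.n_vesicles.mean()),
            "model1_implied_f": m1.implied_f,
            "model1_aged_density_mean": float(m1.aged_dry_density.mean()),
            "model2_aged_density_mean": float(m2.aged_dry_density.mean()),
            "model2_implied_vesicle_conc_gdl": float(
                np.mean(m2.implied_vesicle_conc_gdl)
            ),
            "model2_conc_infeasible": bool(
                np.mean(m2.implied_vesicle_conc_gdl) > config.infeasible_conc_gdl
            ),
            "monotone_violations": m1.monotone_violations + m2.monotone_violations,
        }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}"
        ) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    log.info("pipeline complete; outputs in %s", outdir)
    return summary
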