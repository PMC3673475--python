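"""End-to-end orchestration: simulate -> allocate -> classify -> rrs -> glm.

Runs the full parentage-based RRS analysis on a simulated scenario (or on
tables prepared elsewhere), writing machine-readable reports plus a
MANIFEST recording the seed, a config hash and per-stage completion, so a
failed stage leaves identifiable partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allocation import AllocationConfig, allocate_all, cumulative_allocation
from .genotypes import GenotypeTable
from .glm import (
    MODEL_1,
    MODEL_2,
    MODEL_3,
    UNKNOWN_LEVELS,
    analysis_of_deviance,
    fit_poisson_loglinear,
    predict_mean_rs,
)
from .origins import classify_all, origin_summary
from .rrs import (
    dyad_origin_counts,
    representation_vs_contribution,
    reproductive_success,
    rrs_by_group,
)
from .simulate import ScenarioConfig, ScenarioTruth, generate_scenario

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    allocation: AllocationConfig = field(default_factory=AllocationConfig)
    n_boot: int = 10000
    seed: int = 0
    run_cumulative: bool = False
    outdir: str | Path | None = None


def _config_hash(config: PipelineConfig) -> str:
    text = repr((asdict(config.scenario), asdict(config.allocation),
                 config.n_boot, config.seed))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _round(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def allocate_cohorts(
    truth: ScenarioTruth, config: AllocationConfig
) -> pd.DataFrame:
    """Allocate each fry cohort against the collected spawners of its spawn
    year (incomplete-genotype adults are dropped, as the engine requires)."""
    parts = []
    for year in truth.config.years:
        cand = truth.spawners.subset_individuals(
            truth.spawner_ids_for_year(year)
        ).drop_incomplete()
        off = truth.offspring.subset_individuals(truth.offspring_ids_for_year(year))
        res = allocate_all(off, cand, config)
        res["year"] = year
        parts.append(res)
    return pd.concat(parts, ignore_index=True)


def classify_spawner_origins(
    truth: ScenarioTruth, config: AllocationConfig
) -> pd.DataFrame:
    """Classify returning adults against the broodstock pool.

    The broodstock allocation relaxes the incompatible-locus cap to 1; the
    fry-stocked call itself then requires at most one incompatible allele.
    """
    adults = truth.records[truth.records["pool"] == "run"].copy()
    complete_ids = [
        i for i in truth.spawners.ids
        if bool((truth.spawners.row(i) != -1).all())
    ]
    brood_cfg = replace(config, max_incompatible_loci=1)
    alloc = allocate_all(
        truth.spawners.subset_individuals(complete_ids),
        truth.broodstock,
        brood_cfg,
    )
    calls = classify_all(adults, alloc)
    return calls


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute the full analysis and return the report bundle.

    When ``config.outdir`` is set, writes allocations.csv, origins.csv,
    rs_table.csv, rrs_report.json, contingency_report.json, glm_report.json
    and MANIFEST.json.
    """
    config = config or PipelineConfig()
    scenario_cfg = replace(config.scenario, seed=config.seed)
    alloc_cfg = replace(config.allocation, seed=config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}

    def done(stage: str) -> None:
        manifest["stages"][stage] = "complete"
        if outdir:
            (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    try:
        truth = generate_scenario(scenario_cfg)
        bundle["truth"] = truth
        done("simulate")

        allocations = allocate_cohorts(truth, alloc_cfg)
        bundle["allocations"] = allocations
        if outdir:
            allocations.to_csv(outdir / "allocations.csv", index=False)
        if config.run_cumulative:
            year = truth.config.years[0]
            cand = truth.spawners.subset_individuals(
                truth.spawner_ids_for_year(year)
            ).drop_incomplete()
            off = truth.offspring.subset_individuals(
                truth.offspring_ids_for_year(year)
            )
            bundle["cumulative"] = cumulative_allocation(off, cand, alloc_cfg)
        done("allocate")

        origins = classify_spawner_origins(truth, alloc_cfg)
        bundle["origins"] = origins
        if outdir:
            origins.to_csv(outdir / "origins.csv", index=False)
        done("classify")

        run_meta = truth.records[truth.records["pool"] == "run"].copy()
        rs_table = reproductive_success(allocations, run_meta)
        rs_table = rs_table.merge(
            origins[["id", "origin"]].rename(columns={"origin": "origin_called"}),
            on="id",
            how="left",
        )
        rs_table["origin_called"] = rs_table["origin_called"].fillna("unknown")
        stage_of = {"wild": "wild", "fry_stocked": "fry",
                    "smolt_stocked": "smolt", "unknown": "unknown"}
        rs_table["stockstage_called"] = rs_table["origin_called"].map(stage_of)
        bundle["rs_table"] = rs_table
        if outdir:
            rs_table.to_csv(outdir / "rs_table.csv", index=False)

        est = rrs_by_group(
            rs_table.drop(columns=["origin"]).rename(
                columns={"origin_called": "origin"}
            ),
            group_col="origin",
            focal="hatchery",
            reference="wild",
            n_boot=config.n_boot,
            seed=config.seed,
        )
        rrs_report = {
            "pooled_hatchery_vs_wild": {
                "point": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_boot": est.n_boot,
                "n_focal": est.n_focal,
                "n_reference": est.n_reference,
            },
            "seed": config.seed,
            "config_hash": manifest["config_hash"],
        }
        bundle["rrs_report"] = rrs_report
        if outdir:
            (outdir / "rrs_report.json").write_text(
                json.dumps(_round(rrs_report), indent=2, sort_keys=True)
            )
        done("rrs")

        contingency = {}
        summary = origin_summary(origins, years=list(truth.config.years))
        for year in truth.config.years:
            origin_by_id = origins.set_index("id")["origin"]
            year_alloc = allocations[allocations["year"] == year]
            n_h, n_w = dyad_origin_counts(year_alloc, origin_by_id)
            if n_h + n_w == 0:
                continue
            contingency[str(year)] = representation_vs_contribution(
                int(summary.loc["hatchery", year]),
                int(summary.loc["wild", year]),
                n_h,
                n_w,
            )
        contingency["seed"] = config.seed
        contingency["config_hash"] = manifest["config_hash"]
        bundle["contingency_report"] = contingency
        if outdir:
            (outdir / "contingency_report.json").write_text(
                json.dumps(_round(contingency), indent=2, sort_keys=True)
            )
        done("contingency")

        glm_input = rs_table.rename(
            columns={"stockstage_called": "stockstage_est"}
        ).copy()
        glm_input["stockstage"] = glm_input["stockstage_est"]
        usable = pd.Series(True, index=glm_input.index)
        for term in ("year", "seawinter", "stockstage", "sex"):
            col = "sea_winters" if term == "seawinter" else term
            if col in glm_input.columns:
                usable &= ~glm_input[col].astype(object).isin(UNKNOWN_LEVELS)
        glm_rows = glm_input[usable].rename(columns={"sea_winters": "seawinter"})
        glm_report: dict = {"models": {}, "seed": config.seed,
                            "config_hash": manifest["config_hash"]}
        fits = []
        for spec in (MODEL_1, MODEL_2, MODEL_3):
            fit = fit_poisson_loglinear(glm_rows, spec)
            fits.append(fit)
            glm_report["models"][spec.name] = {
                "formula": spec.formula(),
                "deviance": fit.deviance,
                "df": fit.df_resid,
                "n": fit.n,
                "converged": fit.converged,
                "dispersion": fit.dispersion,
                "coefficients": fit.coefficients.to_dict(),
                "std_errors": fit.std_errors.to_dict(),
            }
        glm_report["comparisons"] = {
            f"model1_vs_{f.spec.name}": analysis_of_deviance(fits[0], f)
            for f in fits[1:]
        }
        # predicted group means from the full model, for the latest year
        # (the year whose hatchery representation is best estimated)
        year = str(max(truth.config.years))
        pred_rows = []
        for sw in ("MSW", "SSW"):
            for stage in ("wild", "fry", "smolt"):
                for sex in ("F", "M"):
                    profile = {"year": year, "seawinter": sw,
                               "stockstage": stage, "sex": sex}
                    try:
                        mean = predict_mean_rs(fits[0], profile)
                    except ValueError:
                        continue
                    pred_rows.append({**profile, "predicted_rs": mean})
        predicted = pd.DataFrame(pred_rows)
        bundle["predicted_means"] = predicted
        if outdir:
            predicted.to_csv(outdir / "predicted_means.csv", index=False)
        bundle["glm_fits"] = fits
        bundle["glm_report"] = glm_report
        if outdir:
            (outdir / "glm_report.json").write_text(
                json.dumps(_round(glm_report), indent=2, sort_keys=True)
            )
        done("glm")
    except Exception:
        if outdir:
            (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise
    return bundle
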