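"""Forward simulator for supportive-breeding parentage scenarios.

Generates a complete synthetic dataset with the statistical structure the
analysis assumes: highly polymorphic microsatellite loci, yearly spawner
pools mixing wild-born and hatchery-born (fry- or smolt-stocked) adults,
a small hatchery broodstock founder pool (which makes hatchery-born
spawners related), uncollected parr sires, Mendelian transmission with
repeat-unit scoring errors, and Poisson-like offspring counts whose group
ratio realises a configured relative reproductive success.  The true
pedigree and parameters are retained so every pipeline stage can be scored
against truth.

Hatchery fitness multipliers are calibrated at generation time so that the
expected pooled hatchery:wild RS ratio equals ``true_rrs`` even when
sea-winter and sex compositions differ between origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeTable,
    LocusDef,
)
from .allocation import inject_offset_errors, mendelian_offspring

DEFAULT_LOCUS_NAMES = (
    "SsaD71",
    "SsaD144",
    "SsaD85",
    "SsaD170",
    "SSa197",
    "Ssosl417",
    "Sssp2201",
    "Sssp2213",
)


@dataclass
class ScenarioConfig:
    """Study-condition parameters of the synthetic scenario.

    Defaults emulate a three-year monitoring program of a small supportive-
    breeding Atlantic salmon population: eight loci with 14-51 alleles,
    per-year spawner pools of a few hundred with the observed wild /
    fry-stocked / smolt-stocked mix, a ~20-founder broodstock, 25-30% of
    offspring-parent dyads involving uncollected parents (mature parr),
    and conservative scoring-error rates of 5% (one repeat unit) and 1%
    (two units).
    """

    years: tuple[int, ...] = (2002, 2003, 2004)
    n_loci: int = 8
    alleles_per_locus: tuple[int, int] = (14, 51)
    motif_length: int = 4
    allele_base_size: int = 100
    n_wild_spawners: Mapping[int, int] = field(
        default_factory=lambda: {2002: 120, 2003: 167, 2004: 206}
    )
    n_fry_stocked: Mapping[int, int] = field(
        default_factory=lambda: {2002: 1, 2003: 16, 2004: 91}
    )
    n_smolt_stocked: Mapping[int, int] = field(
        default_factory=lambda: {2002: 14, 2003: 70, 2004: 51}
    )
    n_offspring_sampled: Mapping[int, int] = field(
        default_factory=lambda: {2002: 226, 2003: 421, 2004: 494}
    )
    n_broodstock_founders: int = 20
    parr_pool_size: int = 100
    unsampled_dyad_fraction: float = 0.275
    # sea-winter composition: probability of returning as MSW, per stage
    p_msw: Mapping[str, float] = field(
        default_factory=lambda: {"wild": 0.385, "fry": 0.333, "smolt": 0.127}
    )
    p_female: float = 0.25
    sex_unknown_rate: float = 0.31
    # fitness structure (multiplicative weights on the expected RS scale)
    true_rrs: float = 0.55
    ssw_weight: float = 0.27  # SSW vs MSW expected-RS ratio
    male_weight: float = 0.44  # male vs female expected-RS ratio
    error_rate_1off: float = 0.05
    error_rate_2off: float = 0.01
    missing_rate_adults: float = 0.013  # per adult per locus
    missing_rate_offspring: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "unsampled_dyad_fraction",
            "p_female",
            "sex_unknown_rate",
            "error_rate_1off",
            "error_rate_2off",
            "missing_rate_adults",
            "missing_rate_offspring",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.alleles_per_locus
        if not 1 <= lo <= hi:
            raise ValueError("alleles_per_locus range is empty")
        for y in self.years:
            total = (
                self.n_wild_spawners[y]
                + self.n_fry_stocked[y]
                + self.n_smolt_stocked[y]
            )
            if total < 2 and self.n_offspring_sampled[y] > 0:
                raise ValueError(
                    f"year {y}: offspring demanded from fewer than 2 spawners"
                )


@dataclass
class ScenarioTruth:
    """Synthetic dataset plus everything needed to score the pipeline."""

    config: ScenarioConfig
    loci: list[LocusDef]
    freqs: AlleleFrequencyTable
    spawners: GenotypeTable  # anadromous run, all years (may contain MISSING)
    broodstock: GenotypeTable
    parr: GenotypeTable  # uncollected sires; withheld from candidate files
    offspring: GenotypeTable
    records: pd.DataFrame  # id, pool, year, sex, sea_winters, scale flag, origin
    pedigree: pd.DataFrame  # offspring_id, parent1, parent2, collected flags, year
    hatchery_weight: float  # calibrated origin multiplier

    def spawner_ids_for_year(self, year: int) -> list[str]:
        mask = (self.records["pool"] == "run") & (self.records["year"] == year)
        return self.records.loc[mask, "id"].tolist()

    def offspring_ids_for_year(self, year: int) -> list[str]:
        mask = (self.records["pool"] == "offspring") & (self.records["year"] == year)
        return self.records.loc[mask, "id"].tolist()

    def true_rs_table(self) -> pd.DataFrame:
        """Per-spawner true counts of sampled offspring, with covariates."""
        counts: dict[str, int] = {}
        for col in ("parent1", "parent2"):
            for pid in self.pedigree[col]:
                counts[pid] = counts.get(pid, 0) + 1
        run = self.records[self.records["pool"] == "run"].copy()
        run["rs"] = run["id"].map(counts).fillna(0).astype(int)
        return run

    def true_rrs(self) -> float:
        """Realised pooled hatchery:wild ratio of true mean RS."""
        rs = self.true_rs_table()
        hatch = rs.loc[rs["origin"].isin(["fry_stocked", "smolt_stocked"]), "rs"]
        wild = rs.loc[rs["origin"] == "wild", "rs"]
        return float(hatch.mean() / wild.mean())


def _make_loci(config: ScenarioConfig) -> list[LocusDef]:
    names = list(DEFAULT_LOCUS_NAMES)[: config.n_loci]
    names += [f"Loc{k}" for k in range(len(names), config.n_loci)]
    return [LocusDef(n, config.motif_length) for n in names]


def _make_freqs(
    loci: list[LocusDef], config: ScenarioConfig, rng: np.random.Generator
) -> AlleleFrequencyTable:
    lo, hi = config.alleles_per_locus
    freqs = {}
    for j, locus in enumerate(loci):
        k = int(rng.integers(lo, hi + 1))
        sizes = config.allele_base_size + config.motif_length * np.arange(k)
        p = rng.dirichlet(np.ones(k))
        freqs[locus.name] = {int(s): float(pi) for s, pi in zip(sizes, p)}
    return AlleleFrequencyTable(loci, freqs)


def _expected_weight(p_msw: float, p_female: float, config: ScenarioConfig) -> float:
    sw = p_msw + (1.0 - p_msw) * config.ssw_weight
    sex = p_female + (1.0 - p_female) * config.male_weight
    return sw * sex


def _calibrate_hatchery_weight(config: ScenarioConfig) -> float:
    """Origin multiplier such that the expected pooled hatchery:wild mean-RS
    ratio equals ``true_rrs`` despite composition differences."""
    w_wild = _expected_weight(config.p_msw["wild"], config.p_female, config)
    n_fry = sum(config.n_fry_stocked.values())
    n_smolt = sum(config.n_smolt_stocked.values())
    w_fry = _expected_weight(config.p_msw["fry"], config.p_female, config)
    w_smolt = _expected_weight(config.p_msw["smolt"], config.p_female, config)
    w_hatch = (n_fry * w_fry + n_smolt * w_smolt) / max(n_fry + n_smolt, 1)
    return config.true_rrs * w_wild / w_hatch


def generate_scenario(config: ScenarioConfig | None = None) -> ScenarioTruth:
    """Build a full synthetic scenario from one integer seed.

    All randomness flows from ``config.seed`` through named sub-streams per
    stage, so the output is byte-identical across runs.
    """
    config = config or ScenarioConfig()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("freqs", "genotypes", "metadata", "mating", "errors", "missing"),
            root.spawn(6),
        )
    }
    loci = _make_loci(config)
    motifs = np.array([l.motif_length for l in loci], dtype=np.int64)
    freqs = _make_freqs(loci, config, streams["freqs"])
    grng = streams["genotypes"]
    mrng = streams["metadata"]

    # broodstock founders: the captive pool of wild-caught breeders
    n_found = config.n_broodstock_founders
    brood_alleles = freqs.sample_genotypes(n_found, grng)
    broodstock = GenotypeTable(
        loci, [f"BS{k:03d}" for k in range(n_found)], brood_alleles,
        pools=["broodstock"] * n_found,
    )

    records: list[dict] = []
    spawner_ids: list[str] = []
    spawner_alleles: list[np.ndarray] = []

    def add_spawner(sid, year, origin, stage):
        is_msw = mrng.random() < config.p_msw[stage]
        u = mrng.random()
        if u < config.sex_unknown_rate:
            sex = "U"
        else:
            sex = "F" if mrng.random() < config.p_female else "M"
        records.append(
            {
                "id": sid,
                "pool": "run",
                "year": year,
                "sex": sex,
                "sea_winters": "MSW" if is_msw else "SSW",
                "scale_smolt_flag": origin == "smolt_stocked",
                "origin": origin,
                "stockstage": {"wild": "wild", "fry_stocked": "fry",
                               "smolt_stocked": "smolt"}[origin],
            }
        )

    for year in config.years:
        for k in range(config.n_wild_spawners[year]):
            sid = f"W{year}_{k:04d}"
            spawner_ids.append(sid)
            spawner_alleles.append(freqs.sample_genotypes(1, grng)[0])
            add_spawner(sid, year, "wild", "wild")
        # hatchery-born returnees are offspring of broodstock founder pairs
        for stage, n in (("fry", config.n_fry_stocked[year]),
                         ("smolt", config.n_smolt_stocked[year])):
            for k in range(n):
                sid = f"H{stage[0].upper()}{year}_{k:04d}"
                ia, ib = grng.choice(n_found, size=2, replace=False)
                child = mendelian_offspring(
                    brood_alleles[[ia]], brood_alleles[[ib]], grng
                )[0]
                spawner_ids.append(sid)
                spawner_alleles.append(child)
                add_spawner(sid, year, f"{stage}_stocked", stage)

    spawner_array = np.stack(spawner_alleles)
    # per-locus amplification failure on adults
    miss = streams["missing"].random((len(spawner_ids), config.n_loci))
    spawner_array[miss < config.missing_rate_adults] = MISSING
    run_records = pd.DataFrame(records)
    spawners = GenotypeTable(loci, spawner_ids, spawner_array,
                             pools=["run"] * len(spawner_ids))
    for rec in records:
        rec["genotype_complete"] = bool(
            (spawners.row(rec["id"]) != MISSING).all()
        )

    # uncollected parr sires (allele frequencies default to the wild pool's)
    parr_ids, parr_records = [], []
    for year in config.years:
        for k in range(config.parr_pool_size):
            parr_ids.append(f"P{year}_{k:04d}")
            parr_records.append(
                {"id": parr_ids[-1], "pool": "parr", "year": year, "sex": "M",
                 "sea_winters": "U", "scale_smolt_flag": False, "origin": "wild",
                 "stockstage": "wild", "genotype_complete": True}
            )
    parr = GenotypeTable(
        loci, parr_ids, freqs.sample_genotypes(len(parr_ids), grng),
        pools=["parr"] * len(parr_ids),
    )

    # fitness weights and offspring generation
    hw = _calibrate_hatchery_weight(config)
    rec_by_id = {r["id"]: r for r in records}
    mate_rng = streams["mating"]
    err_rng = streams["errors"]
    ped_rows: list[dict] = []
    off_ids: list[str] = []
    off_alleles: list[np.ndarray] = []
    for year in config.years:
        ids_y = [s for s in spawner_ids if rec_by_id[s]["year"] == year]
        w = np.array(
            [
                (1.0 if rec_by_id[s]["origin"] == "wild" else hw)
                * (1.0 if rec_by_id[s]["sea_winters"] == "MSW" else config.ssw_weight)
                * _sex_weight(rec_by_id[s]["sex"], config)
                for s in ids_y
            ]
        )
        w /= w.sum()
        idx = {s: spawners._id_index[s] for s in ids_y}
        parr_year = [p for p in parr_ids if p.startswith(f"P{year}_")]
        n_off = config.n_offspring_sampled[year]
        p1 = mate_rng.choice(len(ids_y), size=n_off, p=w)
        p2 = mate_rng.choice(len(ids_y), size=n_off, p=w)
        clash = p1 == p2
        while clash.any():
            p2[clash] = mate_rng.choice(len(ids_y), size=int(clash.sum()), p=w)
            clash = p1 == p2
        # each parental slot is independently held by an uncollected parr
        # with the configured dyad probability
        use_parr1 = mate_rng.random(n_off) < config.unsampled_dyad_fraction
        use_parr2 = mate_rng.random(n_off) < config.unsampled_dyad_fraction
        parr_pick1 = mate_rng.integers(0, len(parr_year), size=n_off)
        parr_pick2 = mate_rng.integers(0, len(parr_year), size=n_off)
        same_parr = use_parr1 & use_parr2 & (parr_pick1 == parr_pick2)
        parr_pick2[same_parr] = (parr_pick2[same_parr] + 1) % len(parr_year)
        first_ids = [
            parr_year[parr_pick1[t]] if use_parr1[t] else ids_y[p1[t]]
            for t in range(n_off)
        ]
        second_ids = [
            parr_year[parr_pick2[t]] if use_parr2[t] else ids_y[p2[t]]
            for t in range(n_off)
        ]
        # adults with amplification failures are still true parents:
        # transmission uses their actual alleles, with a fresh frequency
        # draw standing in for loci whose stored genotype is missing
        def slot_alleles(slot_ids, parr_used):
            return _fill_missing(
                np.stack(
                    [
                        parr.row(sid) if parr_used[t] else spawner_array[idx[sid]]
                        for t, sid in enumerate(slot_ids)
                    ]
                ),
                freqs,
                err_rng,
            )

        a1 = slot_alleles(first_ids, use_parr1)
        a2 = slot_alleles(second_ids, use_parr2)
        child = mendelian_offspring(a1, a2, err_rng)
        child = inject_offset_errors(
            child, motifs, config.error_rate_1off, config.error_rate_2off, err_rng
        )
        cmiss = streams["missing"].random((n_off, config.n_loci))
        child[cmiss < config.missing_rate_offspring] = MISSING
        for t in range(n_off):
            oid = f"F{year + 1}_{t:04d}"  # fry cohort of the following spring
            off_ids.append(oid)
            off_alleles.append(child[t])
            pa, pb = sorted([first_ids[t], second_ids[t]])
            ped_rows.append(
                {
                    "offspring_id": oid,
                    "parent1": pa,
                    "parent2": pb,
                    "parent1_collected": not pa.startswith("P"),
                    "parent2_collected": not pb.startswith("P"),
                    "year": year,
                }
            )
            records_offspring = {
                "id": oid, "pool": "offspring", "year": year, "sex": "U",
                "sea_winters": "U", "scale_smolt_flag": False,
                "origin": "unknown", "stockstage": "unknown",
                "genotype_complete": bool((child[t] != MISSING).all()),
            }
            records.append(records_offspring)

    offspring = GenotypeTable(loci, off_ids, np.stack(off_alleles),
                              pools=["offspring"] * len(off_ids))
    all_records = pd.DataFrame(records + parr_records)
    pedigree = pd.DataFrame(ped_rows)
    return ScenarioTruth(
        config=config,
        loci=loci,
        freqs=freqs,
        spawners=spawners,
        broodstock=broodstock,
        parr=parr,
        offspring=offspring,
        records=all_records,
        pedigree=pedigree,
        hatchery_weight=hw,
    )


def _sex_weight(sex: str, config: ScenarioConfig) -> float:
    if sex == "M":
        return config.male_weight
    if sex == "F":
        return 1.0
    return (1.0 + config.male_weight) / 2.0


def _fill_missing(
    alleles: np.ndarray, freqs: AlleleFrequencyTable, rng: np.random.Generator
) -> np.ndarray:
    """Replace MISSING cells by fresh frequency draws (true alleles exist
    even when the adult's stored genotype failed to amplify)."""
    out = alleles.copy()
    for j, locus in enumerate(freqs.loci):
        mask = out[:, j, 0] == MISSING
        if mask.any():
            pool, probs = freqs.alleles_and_probs(locus.name)
            out[mask, j, :] = rng.choice(pool, size=(int(mask.sum()), 2), p=probs)
    return out
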