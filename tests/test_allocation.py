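"""Allocation engine: pair costs, admissibility, simulation tools."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spawnrs as s
from spawnrs.allocation import (
    UNSAMPLED,
    allocate_all,
    allocate_offspring,
    cumulative_allocation,
    estimate_correct_allocation_rate,
    inject_offset_errors,
    locus_pair_cost,
    score_against_truth,
    simulate_pseudo_offspring,
)
from spawnrs.genotypes import GenotypeTable, LocusDef

from ._oracle import brute_force_allocate, random_instance
from .conftest import random_table, uniform_freqs


class TestLocusPairCost:
    @pytest.mark.parametrize(
        "off,pa,pb,motif,max_offset,expected",
        [
            ((120, 124), (120, 128), (124, 126), 4, 2, 0),  # exact match
            ((120, 124), (112, 128), (124, 126), 4, 2, 2),  # two-unit offset
            ((120, 124), (100, 104), (124, 126), 4, 1, math.inf),
        ],
    )
    def test_examples(self, off, pa, pb, motif, max_offset, expected):
        assert locus_pair_cost(off, pa, pb, motif, max_offset) == expected

    def test_missing_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            locus_pair_cost((120, -1), (120, 128), (124, 126), 4, 2)

    def test_symmetric_in_parents(self, rng):
        for _ in range(50):
            g = lambda: tuple(100 + 4 * rng.integers(0, 8, size=2))
            off, pa, pb = g(), g(), g()
            assert locus_pair_cost(off, pa, pb, 4, 2) == locus_pair_cost(
                off, pb, pa, 4, 2
            )


def _engine_on_instance(off, candidates, motifs, max_offset, budget, cap):
    loci = [LocusDef(f"L{l}", motifs[l]) for l in range(len(motifs))]
    ids = sorted(candidates)
    alleles = np.array([candidates[i] for i in ids])
    table = GenotypeTable(loci, ids, alleles)
    cfg = s.AllocationConfig(
        max_offset=max_offset, offset_budget=budget, max_incompatible_loci=cap
    )
    return allocate_offspring(np.array(off), table, cfg)


class TestOracleEquivalence:
    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_brute_force(self, seed):
        """The engine agrees with exhaustive enumeration on small instances."""
        inst = random_instance(np.random.default_rng(seed))
        status, p1, p2, n_bad, cost = brute_force_allocate(*inst)
        rec = _engine_on_instance(*inst)
        assert rec["status"] == status
        if status in ("pair", "single"):
            assert (rec["parent1"], rec["parent2"]) == (p1, p2)
            assert rec["total_offset_cost"] == cost
            assert rec["n_incompatible_loci"] == n_bad


class TestAllocateOffspring:
    def test_error_free_trio_recovered(self, rng):
        cand = random_table(rng, n=50, n_loci=8)
        dam, sire = cand.alleles[3], cand.alleles[17]
        pick = rng.integers(0, 2, size=(8, 2))
        off = np.stack(
            [dam[np.arange(8), pick[:, 0]], sire[np.arange(8), pick[:, 1]]], axis=1
        )
        rec = allocate_offspring(off, cand)
        assert rec["status"] == "pair"
        assert {rec["parent1"], rec["parent2"]} == {cand.ids[3], cand.ids[17]}
        assert rec["total_offset_cost"] == 0

    def test_removed_dam_gives_single(self, rng):
        cand = random_table(rng, n=50, n_loci=8)
        dam, sire = cand.alleles[3], cand.alleles[17]
        pick = rng.integers(0, 2, size=(8, 2))
        off = np.stack(
            [dam[np.arange(8), pick[:, 0]], sire[np.arange(8), pick[:, 1]]], axis=1
        )
        reduced = cand.subset_individuals([i for i in cand.ids if i != cand.ids[3]])
        rec = allocate_offspring(off, reduced)
        assert rec["status"] == "single"
        assert rec["parent1"] == cand.ids[17]
        assert rec["parent2"] == UNSAMPLED

    def test_identical_candidate_pairs_are_ambiguous(self):
        loci = [LocusDef(f"L{j}", 4) for j in range(3)]
        geno = np.array([[100, 104], [120, 128], [140, 140]])
        other = np.array([[104, 108], [120, 124], [140, 144]])
        alleles = np.stack([geno, geno, other, other])
        cand = GenotypeTable(loci, ["a", "b", "c", "d"], alleles)
        off = np.array([[100, 108], [120, 124], [140, 144]])
        rec = allocate_offspring(off, cand)
        assert rec["status"] == "ambiguous"

    def test_empty_candidates(self):
        loci = [LocusDef("L0", 4)]
        cand = GenotypeTable(loci, [], np.empty((0, 1, 2), dtype=int))
        rec = allocate_offspring(np.array([[100, 104]]), cand)
        assert rec["status"] == "none"


class TestAllocateAll:
    def test_all_collected_zero_error(self, rng):
        freqs = uniform_freqs(n_loci=8, n_alleles=25)
        cfg = s.AllocationConfig(
            error_rate_1off=0, error_rate_2off=0, n_pseudo_offspring=100, seed=5
        )
        sim = simulate_pseudo_offspring(freqs, cfg, n_parents=100)
        res = allocate_all(sim.offspring, sim.collected, cfg)
        correct = score_against_truth(res, sim.truth, set(sim.collected.ids))
        assert (res["status"] == "pair").all()
        assert correct.all()

    def test_empty_offspring(self, rng):
        cand = random_table(rng, n=10, n_loci=2)
        off = GenotypeTable(cand.loci, [], np.empty((0, 2, 2), dtype=int))
        assert len(allocate_all(off, cand)) == 0

    def test_incomplete_offspring_flagged_not_dropped(self, rng):
        cand = random_table(rng, n=10, n_loci=2)
        alleles = cand.alleles[:2].copy()
        alleles[1, 0, :] = -1
        off = GenotypeTable(cand.loci, ["o1", "o2"], alleles)
        res = allocate_all(off, cand)
        assert len(res) == 2
        assert res.set_index("offspring_id").loc["o2", "status"] == "incomplete"

    def test_deterministic(self, rng):
        freqs = uniform_freqs()
        cfg = s.AllocationConfig(n_pseudo_offspring=50, seed=11)
        sim = simulate_pseudo_offspring(freqs, cfg, n_parents=60)
        r1 = allocate_all(sim.offspring, sim.collected, cfg)
        r2 = allocate_all(sim.offspring, sim.collected, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_mixture_with_uncollected_slots(self, rng):
        """With ~30% of parental slots withheld, pair/single statuses split
        roughly along the 70/30 slot proportion."""
        freqs = uniform_freqs(n_loci=8, n_alleles=30)
        cfg = s.AllocationConfig(
            error_rate_1off=0,
            error_rate_2off=0,
            n_pseudo_offspring=400,
            n_uncollected_parents=90,
            seed=7,
        )
        sim = simulate_pseudo_offspring(freqs, cfg, n_parents=300)
        res = allocate_all(sim.offspring, sim.collected, cfg)
        slots = (2 * (res["status"] == "pair").sum() + (res["status"] == "single").sum())
        collected_fraction = slots / (2 * len(res))
        assert collected_fraction == pytest.approx(0.7, abs=0.06)


class TestMonotonicity:
    def test_added_locus_never_rescues_incompatible_pair(self, rng):
        """If a true pair is incompatible on a locus prefix it stays
        incompatible when more loci are added."""
        for _ in range(30):
            g = lambda n: 100 + 4 * rng.integers(0, 10, size=(n, 2))
            pa, pb = g(5), g(5)
            off = g(5)
            incompat = [
                math.isinf(
                    locus_pair_cost(tuple(off[l]), tuple(pa[l]), tuple(pb[l]), 4, 1)
                )
                for l in range(5)
            ]
            for prefix in range(1, 5):
                if any(incompat[:prefix]):
                    assert any(incompat[: prefix + 1])


class TestPseudoOffspring:
    def test_zero_error_fully_compatible(self):
        freqs = uniform_freqs()
        cfg = s.AllocationConfig(
            error_rate_1off=0, error_rate_2off=0, n_pseudo_offspring=50, seed=3
        )
        sim = simulate_pseudo_offspring(freqs, cfg, n_parents=40)
        for k, oid in enumerate(sim.offspring.ids):
            row = sim.truth.iloc[k]
            pa = sim.parents.row(row["parent1"])
            pb = sim.parents.row(row["parent2"])
            for l, locus in enumerate(freqs.loci):
                c = locus_pair_cost(
                    tuple(sim.offspring.row(oid)[l]),
                    tuple(pa[l]),
                    tuple(pb[l]),
                    locus.motif_length,
                    cfg.max_offset,
                )
                assert c == 0

    def test_error_fraction_matches_closed_form(self):
        """P(at least one shifted allele) = 1 - (1-e1-e2)^(2L)."""
        freqs = uniform_freqs(n_loci=8)
        cfg = s.AllocationConfig(n_pseudo_offspring=4000, seed=9)
        rng = np.random.default_rng(9)
        clean = np.zeros((4000, 8, 2), dtype=np.int64)
        shifted = inject_offset_errors(
            clean, np.full(8, 4, dtype=np.int64), 0.05, 0.01, rng
        )
        frac = ((shifted != clean).any(axis=(1, 2))).mean()
        expected = 1 - (1 - 0.06) ** 16
        assert frac == pytest.approx(expected, abs=0.025)

    def test_seed_reproducibility(self):
        freqs = uniform_freqs()
        cfg = s.AllocationConfig(n_pseudo_offspring=30, seed=21)
        a = simulate_pseudo_offspring(freqs, cfg, n_parents=30)
        b = simulate_pseudo_offspring(freqs, cfg, n_parents=30)
        assert a.offspring == b.offspring
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_degenerate_single_allele_warns(self):
        loci = [LocusDef("L", 4)]
        freqs = s.AlleleFrequencyTable(loci, {"L": {100: 1.0}})
        cfg = s.AllocationConfig(n_pseudo_offspring=5, seed=1)
        sim = simulate_pseudo_offspring(freqs, cfg, n_parents=10)
        assert len(sim.offspring) == 5


class TestCorrectAllocationRate:
    def test_zero_error_rate_near_one(self):
        freqs = uniform_freqs(n_loci=8, n_alleles=25)
        cfg = s.AllocationConfig(
            error_rate_1off=0,
            error_rate_2off=0,
            n_pseudo_offspring=300,
            n_iterations=2,
            seed=13,
        )
        cand = GenotypeTable(
            freqs.loci,
            [f"C{k}" for k in range(200)],
            freqs.sample_genotypes(200, np.random.default_rng(13)),
        )
        report = estimate_correct_allocation_rate(cand, cfg)
        assert report.mean_correct_rate >= 0.99

    def test_report_determinism(self):
        freqs = uniform_freqs(n_loci=6, n_alleles=15)
        cand = GenotypeTable(
            freqs.loci,
            [f"C{k}" for k in range(50)],
            freqs.sample_genotypes(50, np.random.default_rng(2)),
        )
        cfg = s.AllocationConfig(n_pseudo_offspring=100, n_iterations=2, seed=17)
        r1 = estimate_correct_allocation_rate(cand, cfg)
        r2 = estimate_correct_allocation_rate(cand, cfg)
        assert r1.per_iteration_rates == r2.per_iteration_rates


class TestCumulativeAllocation:
    def test_all_collected_converges_to_one(self):
        freqs = uniform_freqs(n_loci=8, n_alleles=25)
        cfg = s.AllocationConfig(
            error_rate_1off=0, error_rate_2off=0, n_pseudo_offspring=150, seed=19
        )
        sim = simulate_pseudo_offspring(freqs, cfg, n_parents=150)
        curve = cumulative_allocation(sim.offspring, sim.collected, cfg)
        assert curve.pair_rate[-1] >= 0.99
        assert curve.uncollected_slot_estimate == pytest.approx(0.0, abs=0.01)

    def test_requires_two_loci(self, rng):
        table = random_table(rng, n=10, n_loci=1)
        with pytest.raises(ValueError, match="2 loci"):
            cumulative_allocation(table, table)


class TestAssignmentPowerBias:
    def test_symmetric_groups_have_similar_rates(self, rng):
        freqs = uniform_freqs(n_loci=8, n_alleles=25)
        g = GenotypeTable(
            freqs.loci,
            [f"A{k}" for k in range(80)],
            freqs.sample_genotypes(80, rng),
        )
        h = GenotypeTable(
            freqs.loci,
            [f"B{k}" for k in range(80)],
            freqs.sample_genotypes(80, rng),
        )
        cfg = s.AllocationConfig(n_pseudo_offspring=400, seed=23)
        report = s.assignment_power_bias(g, h, cfg)
        assert abs(report.per_group_rates["wild"] - report.per_group_rates["hatchery"]) < 0.1

    def test_zero_error_rates_near_one(self, rng):
        freqs = uniform_freqs(n_loci=8, n_alleles=25)
        g = GenotypeTable(
            freqs.loci, [f"A{k}" for k in range(60)], freqs.sample_genotypes(60, rng)
        )
        h = GenotypeTable(
            freqs.loci, [f"B{k}" for k in range(60)], freqs.sample_genotypes(60, rng)
        )
        cfg = s.AllocationConfig(
            error_rate_1off=0, error_rate_2off=0, n_pseudo_offspring=200, seed=29
        )
        report = s.assignment_power_bias(g, h, cfg)
        assert report.per_group_rates["wild"] >= 0.98
        assert report.per_group_rates["hatchery"] >= 0.98

    def test_few_founder_group_attracts_errors(self):
        """Related hatchery parents (few founders) raise the error rate for
        hatchery-born offspring, and errors concentrate stocked->stocked."""
        from spawnrs.simulate import ScenarioConfig, generate_scenario

        truth = generate_scenario(ScenarioConfig(seed=31, missing_rate_adults=0.0))
        run = truth.records[truth.records["pool"] == "run"]
        wild_ids = run.loc[run["origin"] == "wild", "id"].tolist()[:150]
        hatch_ids = run.loc[run["origin"] != "wild", "id"].tolist()[:150]
        cfg = s.AllocationConfig(n_pseudo_offspring=4000, seed=31)
        report = s.assignment_power_bias(
            truth.spawners.subset_individuals(wild_ids),
            truth.spawners.subset_individuals(hatch_ids),
            cfg,
        )
        assert report.per_group_rates["hatchery"] < report.per_group_rates["wild"]
        # misassignments (errors landing on a wrong parent pair) from
        # hatchery-born offspring overwhelmingly hit other hatchery parents
        m = report.error_matrix
        assigned = m.loc["hatchery"].drop("unallocated", errors="ignore")
        assert assigned.sum() > 0
        assert assigned.get("hatchery", 0) / assigned.sum() > 0.8
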