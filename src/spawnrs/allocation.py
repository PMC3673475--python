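"""Offset-tolerant exclusion-based parental allocation.

Implements a restricted scoring-error tolerance approach to parentage: an
offspring allele may be attributed to a candidate parent if it lies within
``max_offset`` tandem-repeat units of one of the parent's alleles, and a
candidate pair is admissible if the number of incompatible loci and the
summed offset cost both stay within configured caps.  The unique admissible
pair minimising ``(n_incompatible_loci, total_offset_cost)`` is returned;
exact ties leave the offspring unallocated.  When no pair is admissible a
single-parent allocation is attempted, realising the "one collected + one
uncollected parent" outcome without modelling the missing genotype.

The module also provides the two simulation tools built on the same engine:
pseudo-offspring generation from empirical allele frequencies (used to
estimate the expected correct-allocation rate) and cumulative allocation
over locus prefixes (used to estimate the proportion of uncollected
parents from the levelling-off of the allocation rate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeTable,
    LocusDef,
    allele_frequencies,
)

logger = logging.getLogger(__name__)

#: Identifier used for a parental slot attributed to an uncollected parent.
UNSAMPLED = "UNSAMPLED"

#: Returned by :func:`locus_pair_cost` when no allele assignment exists.
INCOMPATIBLE = math.inf

_BIG = 100.0  # per-locus key stride: bad-allele count dominates offset cost


@dataclass
class AllocationConfig:
    """Tuning knobs of the allocation engine.

    ``max_offset`` is the per-allele scoring-error tolerance in repeat units
    (capped at 2: the error model does not extend beyond two offsets), and
    ``offset_budget`` caps the summed offset cost per offspring across loci.
    The default budget of ``2 * max_offset`` keeps true parents admissible
    under the conservative 5%/1% error model (whose expected summed cost per
    offspring is about 1.1) while still excluding loosely matching pairs.
    ``max_incompatible_loci`` is 0 for fry allocation; origin classification
    of returning adults against the broodstock pool relaxes it to 1.
    ``error_rate_1off``/``error_rate_2off`` are the per-transmitted-allele
    probabilities of a +/-1 and +/-2 repeat-unit scoring error used by the
    pseudo-offspring simulations (deliberately conservative values).
    """

    max_offset: int = 2
    offset_budget: int = 4
    max_incompatible_loci: int = 0
    locus_order: str = "input"  # or "by_exclusion_power"
    tie_rule: str = "unallocated"  # or "lowest_cost_then_unallocated"
    n_pseudo_offspring: int = 1000
    n_iterations: int = 10
    error_rate_1off: float = 0.05
    error_rate_2off: float = 0.01
    n_uncollected_parents: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_offset not in (0, 1, 2):
            raise ValueError("max_offset must be 0, 1 or 2")
        for name in ("error_rate_1off", "error_rate_2off"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.error_rate_1off + self.error_rate_2off > 1.0:
            raise ValueError("error rates sum to more than 1")
        if self.n_pseudo_offspring < 1:
            raise ValueError("n_pseudo_offspring must be >= 1")
        if self.locus_order not in ("input", "by_exclusion_power"):
            raise ValueError(f"unknown locus_order {self.locus_order!r}")
        if self.tie_rule not in ("unallocated", "lowest_cost_then_unallocated"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")


RESULT_COLUMNS = [
    "offspring_id",
    "parent1",
    "parent2",
    "status",
    "total_offset_cost",
    "n_incompatible_loci",
    "n_incompatible_alleles",
    "n_loci_used",
]


def locus_pair_cost(
    offspring: tuple[int, int],
    parent_a: tuple[int, int],
    parent_b: tuple[int, int],
    motif_length: int,
    max_offset: int = 2,
) -> float:
    """Minimal summed offset cost of explaining one locus by a parent pair.

    One offspring allele must be drawn from each parent; an allele may be
    drawn from a parent only if its distance (in repeat units) to one of
    that parent's alleles is at most ``max_offset``.  Returns the cost of
    the cheaper of the two assignments, or :data:`INCOMPATIBLE`.
    """
    for pair in (offspring, parent_a, parent_b):
        if MISSING in pair:
            raise ValueError("complete genotypes required for pair cost")

    def supply(parent: tuple[int, int], allele: int) -> float:
        d = min(
            round(abs(allele - parent[0]) / motif_length),
            round(abs(allele - parent[1]) / motif_length),
        )
        return d if d <= max_offset else INCOMPATIBLE

    x, y = offspring
    c1 = supply(parent_a, x) + supply(parent_b, y)
    c2 = supply(parent_a, y) + supply(parent_b, x)
    return min(c1, c2)


class _Engine:
    """Vectorised allocation of offspring against a fixed candidate set."""

    def __init__(self, candidates: GenotypeTable, config: AllocationConfig):
        if not candidates.complete_mask().all():
            raise ValueError(
                "candidate parents must have complete genotypes; "
                "drop incomplete individuals upstream"
            )
        self.candidates = candidates
        self.config = config
        self.ids = np.array(candidates.ids)
        self.alleles = candidates.alleles.astype(np.float64)  # (P, L, 2)
        self.motifs = np.array([l.motif_length for l in candidates.loci], float)
        self.n_loci = len(candidates.loci)

    def distance(self, off: np.ndarray) -> np.ndarray:
        """(P, L, 2) min offset distance to each offspring allele; inf if
        beyond tolerance."""
        diff = np.abs(self.alleles[:, :, :, None] - off[None, :, None, :])
        units = np.rint(diff / self.motifs[None, :, None, None])
        d = units.min(axis=2)  # over the parent's two alleles
        d[d > self.config.max_offset] = np.inf
        return d

    def allocate(self, off: np.ndarray, offspring_id: str) -> dict:
        cfg = self.config
        D = self.distance(off)  # (P, L, 2)
        deficient = np.isinf(D).all(axis=2)  # parent cannot supply either allele
        defc = deficient.sum(axis=1)

        kept = np.flatnonzero(defc <= cfg.max_incompatible_loci)
        if kept.size >= 2:
            found = self._best_pair(D[kept], kept, offspring_id)
            if found is not None:
                return found
        return self._best_single(D, defc, offspring_id)

    def _best_pair(self, Dk: np.ndarray, kept: np.ndarray, oid: str) -> dict | None:
        cfg = self.config
        K = Dk.shape[0]
        s0, s1 = Dk[:, :, 0], Dk[:, :, 1]  # (K, L) supply costs per allele
        f0, f1 = np.isfinite(s0), np.isfinite(s1)
        g0 = np.where(f0, s0, 0.0)
        g1 = np.where(f1, s1, 0.0)
        # per-locus keys of the two allele assignments: bad-count * _BIG + cost
        key1 = (
            (~f0[:, None, :]).astype(np.float64) + (~f1[None, :, :])
        ) * _BIG + (g0[:, None, :] + g1[None, :, :])
        key2 = (
            (~f1[:, None, :]).astype(np.float64) + (~f0[None, :, :])
        ) * _BIG + (g1[:, None, :] + g0[None, :, :])
        key = np.minimum(key1, key2)  # (K, K, L)
        bad = np.floor_divide(key, _BIG)
        cost = key - bad * _BIG
        n_bad_alleles = bad.sum(axis=2)
        n_bad_loci = (bad > 0).sum(axis=2)
        total_cost = cost.sum(axis=2)

        admissible = (n_bad_loci <= cfg.max_incompatible_loci) & (
            total_cost <= cfg.offset_budget
        )
        iu = np.triu_indices(K, k=1)
        adm = admissible[iu]
        if not adm.any():
            return None
        rank = n_bad_loci[iu] * 1e6 + total_cost[iu]
        rank[~adm] = np.inf
        best = rank.min()
        ties = np.flatnonzero(rank == best)
        if ties.size > 1:
            return _record(oid, UNSAMPLED, UNSAMPLED, "ambiguous", 0, 0, 0, self.n_loci)
        t = ties[0]
        i, j = iu[0][t], iu[1][t]
        p1, p2 = sorted([self.ids[kept[i]], self.ids[kept[j]]])
        return _record(
            oid,
            p1,
            p2,
            "pair",
            int(total_cost[i, j]),
            int(n_bad_loci[i, j]),
            int(n_bad_alleles[i, j]),
            self.n_loci,
        )

    def _best_single(self, D: np.ndarray, defc: np.ndarray, oid: str) -> dict:
        cfg = self.config
        ok = defc == 0  # every locus must offer at least one attributable allele
        if ok.any():
            cost = D.min(axis=2).sum(axis=1)
            cost[~ok] = np.inf
            cost[cost > cfg.offset_budget] = np.inf
            best = cost.min()
            if np.isfinite(best):
                ties = np.flatnonzero(cost == best)
                if ties.size > 1:
                    return _record(
                        oid, UNSAMPLED, UNSAMPLED, "ambiguous", 0, 0, 0, self.n_loci
                    )
                return _record(
                    oid,
                    str(self.ids[ties[0]]),
                    UNSAMPLED,
                    "single",
                    int(best),
                    0,
                    0,
                    self.n_loci,
                )
        return _record(oid, UNSAMPLED, UNSAMPLED, "none", 0, 0, 0, self.n_loci)


def _record(oid, p1, p2, status, cost, nloci_bad, nalleles_bad, n_loci) -> dict:
    return {
        "offspring_id": oid,
        "parent1": p1,
        "parent2": p2,
        "status": status,
        "total_offset_cost": cost,
        "n_incompatible_loci": nloci_bad,
        "n_incompatible_alleles": nalleles_bad,
        "n_loci_used": n_loci,
    }


def allocate_offspring(
    offspring_alleles: np.ndarray,
    candidates: GenotypeTable,
    config: AllocationConfig | None = None,
    offspring_id: str = "offspring",
) -> dict:
    """Allocate a single offspring; see :func:`allocate_all` for batches."""
    config = config or AllocationConfig()
    off = np.asarray(offspring_alleles, dtype=np.float64).reshape(-1, 2)
    if (off == MISSING).any():
        raise ValueError("offspring genotype must be complete over the loci used")
    if len(candidates) == 0:
        return _record(
            offspring_id, UNSAMPLED, UNSAMPLED, "none", 0, 0, 0, off.shape[0]
        )
    return _Engine(candidates, config).allocate(off, offspring_id)


def allocate_all(
    offspring: GenotypeTable,
    candidates: GenotypeTable,
    config: AllocationConfig | None = None,
) -> pd.DataFrame:
    """Allocate every offspring independently against the candidate pool.

    Offspring with incomplete genotypes are not allocated; they appear with
    status ``incomplete`` so no row is silently dropped.  Candidates with
    incomplete genotypes must be removed upstream (the engine enforces the
    complete-genotype requirement for parents).
    """
    config = config or AllocationConfig()
    if offspring.locus_names != candidates.locus_names:
        raise ValueError("offspring and candidate tables must share loci")
    rows: list[dict] = []
    if len(candidates) == 0:
        for oid in offspring.ids:
            rows.append(
                _record(oid, UNSAMPLED, UNSAMPLED, "none", 0, 0, 0, len(offspring.loci))
            )
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)
    engine = _Engine(candidates, config)
    complete = offspring.complete_mask()
    n_skipped = int((~complete).sum())
    if n_skipped:
        logger.info("allocate_all: %d offspring with incomplete genotypes", n_skipped)
    for k, oid in enumerate(offspring.ids):
        if not complete[k]:
            rec = _record(
                oid, UNSAMPLED, UNSAMPLED, "incomplete", 0, 0, 0, len(offspring.loci)
            )
        else:
            rec = engine.allocate(offspring.alleles[k].astype(np.float64), oid)
        rows.append(rec)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# Cumulative allocation over locus prefixes


@dataclass
class CumulativeCurve:
    """Allocation-rate curve over locus prefixes and the uncollected-parent
    estimate derived from the full-panel allocation."""

    locus_order: list[str]
    pair_rate: list[float]  # rate of allocation to two collected parents per l
    collected_slot_fraction: float  # at l = L
    uncollected_slot_estimate: float  # 1 - collected fraction
    plateau_detected: bool


def exclusion_power_order(
    candidates: GenotypeTable,
    config: AllocationConfig,
    n_trials: int = 2000,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Order loci by decreasing single-locus exclusion power.

    Power is 1 minus the probability that a random offspring genotype (drawn
    from empirical allele frequencies) is compatible with a random candidate
    pair at that locus, estimated by Monte Carlo.
    """
    rng = rng or np.random.default_rng(config.seed)
    freqs = allele_frequencies(candidates)
    P = len(candidates)
    powers = []
    for j, locus in enumerate(candidates.loci):
        alleles, probs = freqs.alleles_and_probs(locus.name)
        off = rng.choice(alleles, size=(n_trials, 2), p=probs)
        ia = rng.integers(0, P, size=n_trials)
        ib = (ia + 1 + rng.integers(0, P - 1, size=n_trials)) % P
        compat = 0
        for t in range(n_trials):
            c = locus_pair_cost(
                (off[t, 0], off[t, 1]),
                tuple(candidates.alleles[ia[t], j]),
                tuple(candidates.alleles[ib[t], j]),
                locus.motif_length,
                config.max_offset,
            )
            compat += math.isfinite(c)
        powers.append(1.0 - compat / n_trials)
    order = np.argsort(powers)[::-1]  # most excluding first
    return [candidates.loci[k].name for k in order]


def cumulative_allocation(
    offspring: GenotypeTable,
    candidates: GenotypeTable,
    config: AllocationConfig | None = None,
    plateau_tol: float = 0.01,
) -> CumulativeCurve:
    """Allocate on locus prefixes of length 1..L and estimate the share of
    parental slots held by uncollected parents.

    The collected-slot fraction at the full panel counts 2 slots for a
    pair allocation and 1 for a single; its complement estimates the
    uncollected-parent proportion.  The plateau flag reports whether the
    pair-allocation rate has stabilised (relative change below
    ``plateau_tol`` between the last two prefix lengths); without a
    plateau the estimate may still be biased upward.
    """
    config = config or AllocationConfig()
    L = len(offspring.loci)
    if L < 2:
        raise ValueError("cumulative allocation requires at least 2 loci")
    if config.locus_order == "by_exclusion_power":
        order = exclusion_power_order(candidates, config)
    else:
        order = offspring.locus_names
    rates: list[float] = []
    last_result: pd.DataFrame | None = None
    usable = offspring.complete_mask().sum()
    for l in range(1, L + 1):
        prefix = order[:l]
        res = allocate_all(
            offspring.subset_loci(prefix), candidates.subset_loci(prefix), config
        )
        rates.append(
            float((res["status"] == "pair").sum() / max(usable, 1))
        )
        last_result = res
    n_pair = int((last_result["status"] == "pair").sum())
    n_single = int((last_result["status"] == "single").sum())
    collected = (2 * n_pair + n_single) / (2 * max(usable, 1))
    if rates[-2] > 0:
        plateau = abs(rates[-1] - rates[-2]) / rates[-2] < plateau_tol
    else:
        plateau = rates[-1] == rates[-2]
    if not plateau:
        logger.warning(
            "cumulative allocation: no plateau within %d loci; the "
            "uncollected-parent estimate may be overestimated",
            L,
        )
    return CumulativeCurve(
        locus_order=list(order),
        pair_rate=rates,
        collected_slot_fraction=float(collected),
        uncollected_slot_estimate=float(1.0 - collected),
        plateau_detected=bool(plateau),
    )


# ---------------------------------------------------------------------------
# Pseudo-offspring simulation and correctness-rate estimation


@dataclass
class PseudoOffspringSet:
    """Virtual parents, simulated offspring and the true pedigree."""

    parents: GenotypeTable  # all virtual parents, collected first
    collected: GenotypeTable  # candidate set offered to the engine
    offspring: GenotypeTable
    truth: pd.DataFrame  # offspring_id, parent1, parent2, n_collected


@dataclass
class SimulationReport:
    """Correct-allocation rate estimated from pseudo-offspring rounds."""

    mean_correct_rate: float
    per_iteration_rates: list[float]
    error_matrix: pd.DataFrame  # true group x assigned group, erroneous only
    per_group_rates: dict[str, float] = field(default_factory=dict)


def inject_offset_errors(
    alleles: np.ndarray,
    motifs: np.ndarray,
    rate_1off: float,
    rate_2off: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shift each transmitted allele by +/-1 motif unit with probability
    ``rate_1off`` and by +/-2 units with probability ``rate_2off``."""
    out = alleles.copy()
    u = rng.random(out.shape)
    mag = np.zeros(out.shape, dtype=np.int64)
    mag[u < rate_1off] = 1
    mag[(u >= rate_1off) & (u < rate_1off + rate_2off)] = 2
    sign = rng.choice([-1, 1], size=out.shape)
    out += mag * sign * motifs.reshape(1, -1, 1).astype(np.int64)
    return out


def mendelian_offspring(
    parent1: np.ndarray,
    parent2: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one allele per locus from each parent (fair coin); shapes
    ``(n, L, 2) x (n, L, 2) -> (n, L, 2)``."""
    n, L, _ = parent1.shape
    pick1 = rng.integers(0, 2, size=(n, L))
    pick2 = rng.integers(0, 2, size=(n, L))
    a1 = np.take_along_axis(parent1, pick1[:, :, None], axis=2)[:, :, 0]
    a2 = np.take_along_axis(parent2, pick2[:, :, None], axis=2)[:, :, 0]
    return np.stack([a1, a2], axis=2)


def simulate_pseudo_offspring(
    freqs: AlleleFrequencyTable,
    config: AllocationConfig,
    n_parents: int,
    rng: np.random.Generator | None = None,
) -> PseudoOffspringSet:
    """Generate virtual parents by i.i.d. allele resampling from empirical
    frequencies and pseudo-offspring from random parent pairs.

    The last ``config.n_uncollected_parents`` virtual parents are withheld
    from the candidate set, emulating uncollected parents (mature parr and
    adults discarded for incomplete genotypes).  Scoring errors are applied
    to transmitted alleles only.
    """
    rng = rng or np.random.default_rng(config.seed)
    if n_parents <= config.n_uncollected_parents + 1:
        raise ValueError("n_parents must exceed n_uncollected_parents + 1")
    loci = freqs.loci
    motifs = np.array([l.motif_length for l in loci], dtype=np.int64)
    single_allele = all(len(freqs[l.name]) == 1 for l in loci)
    if single_allele:
        logger.warning("degenerate frequencies: a single allele at every locus")

    parent_alleles = freqs.sample_genotypes(n_parents, rng)
    parent_ids = [f"VP{k:05d}" for k in range(n_parents)]
    parents = GenotypeTable(loci, parent_ids, parent_alleles)

    n_off = config.n_pseudo_offspring
    ia = rng.integers(0, n_parents, size=n_off)
    ib = (ia + 1 + rng.integers(0, n_parents - 1, size=n_off)) % n_parents
    child = mendelian_offspring(parent_alleles[ia], parent_alleles[ib], rng)
    child = inject_offset_errors(
        child, motifs, config.error_rate_1off, config.error_rate_2off, rng
    )
    off_ids = [f"PO{k:05d}" for k in range(n_off)]
    offspring = GenotypeTable(loci, off_ids, child)

    n_collected = n_parents - config.n_uncollected_parents
    collected = parents.subset_individuals(parent_ids[:n_collected])
    coll = np.array([ia < n_collected, ib < n_collected]).sum(axis=0)
    truth = pd.DataFrame(
        {
            "offspring_id": off_ids,
            "parent1": [parent_ids[k] for k in ia],
            "parent2": [parent_ids[k] for k in ib],
            "n_collected": coll,
        }
    )
    # canonicalise parent order for comparison with allocation output
    swap = truth["parent1"] > truth["parent2"]
    truth.loc[swap, ["parent1", "parent2"]] = truth.loc[
        swap, ["parent2", "parent1"]
    ].to_numpy()
    return PseudoOffspringSet(parents, collected, offspring, truth)


def score_against_truth(
    result: pd.DataFrame,
    truth: pd.DataFrame,
    collected_ids: set[str],
) -> pd.Series:
    """Per-offspring correctness of an allocation against a true pedigree.

    Correct means: both true parents collected and the allocated pair equals
    the true pair; exactly one collected and a single allocation names it;
    none collected and the offspring was left unallocated.
    """
    merged = result.merge(truth, on="offspring_id", suffixes=("", "_true"))
    t1in = merged["parent1_true"].isin(collected_ids).to_numpy()
    t2in = merged["parent2_true"].isin(collected_ids).to_numpy()
    ncoll = t1in.astype(int) + t2in.astype(int)
    pair_ok = (
        (merged["status"] == "pair")
        & (merged["parent1"] == merged["parent1_true"])
        & (merged["parent2"] == merged["parent2_true"])
    ).to_numpy()
    true_single = merged["parent1_true"].where(t1in, merged["parent2_true"])
    single_ok = (
        (merged["status"] == "single") & (merged["parent1"] == true_single)
    ).to_numpy()
    none_ok = (merged["status"] == "none").to_numpy()
    correct = np.where(ncoll == 2, pair_ok, np.where(ncoll == 1, single_ok, none_ok))
    return pd.Series(correct, index=merged["offspring_id"].to_numpy())


def estimate_correct_allocation_rate(
    candidates: GenotypeTable,
    config: AllocationConfig,
) -> SimulationReport:
    """Point estimate of the correct-allocation rate by repeated rounds of
    pseudo-offspring simulation and re-allocation.

    ``config.n_uncollected_parents`` extra virtual parents are simulated and
    withheld, so the estimate accounts for offspring of uncollected parents;
    the mean over ``config.n_iterations`` rounds is the point estimate.
    """
    rng = np.random.default_rng(config.seed)
    freqs = allele_frequencies(candidates)
    n_parents = len(candidates) + config.n_uncollected_parents
    rates = []
    confusion: dict[tuple[str, str], int] = {}
    for _ in range(config.n_iterations):
        sim = simulate_pseudo_offspring(freqs, config, n_parents, rng)
        result = allocate_all(sim.offspring, sim.collected, config)
        correct = score_against_truth(result, sim.truth, set(sim.collected.ids))
        rates.append(float(correct.mean()))
        wrong = result.loc[~correct.to_numpy(), "status"]
        truth_n = sim.truth.set_index("offspring_id")["n_collected"]
        for oid, status in wrong.items():
            key = (f"{truth_n[result.loc[oid, 'offspring_id']]}_collected", status)
            confusion[key] = confusion.get(key, 0) + 1
    matrix = _confusion_frame(confusion)
    return SimulationReport(float(np.mean(rates)), rates, matrix)


def _confusion_frame(confusion: dict[tuple[str, str], int]) -> pd.DataFrame:
    if not confusion:
        return pd.DataFrame()
    idx = sorted({k[0] for k in confusion})
    cols = sorted({k[1] for k in confusion})
    matrix = pd.DataFrame(0, index=idx, columns=cols)
    for (r, c), v in confusion.items():
        matrix.loc[r, c] = v
    return matrix


def assignment_power_bias(
    wild_parents: GenotypeTable,
    hatchery_parents: GenotypeTable,
    config: AllocationConfig,
) -> SimulationReport:
    """Compare assignment performance between offspring of wild-born and of
    stocked (hatchery-born) parents.

    Pseudo-offspring are generated within each group by Mendelian
    transmission from the actual group genotypes (so any relatedness in the
    hatchery pool carries through), then allocated against the combined
    candidate set.  The error matrix classifies erroneous allocations by the
    true parental group and the group of the wrongly assigned parents.
    """
    if len(wild_parents) < 2 or len(hatchery_parents) < 2:
        raise ValueError("both parent groups must hold at least two individuals")
    if wild_parents.locus_names != hatchery_parents.locus_names:
        raise ValueError("parent groups must share loci")
    rng = np.random.default_rng(config.seed)
    combined = GenotypeTable(
        wild_parents.loci,
        wild_parents.ids + hatchery_parents.ids,
        np.concatenate([wild_parents.alleles, hatchery_parents.alleles]),
    )
    group_of = {i: "wild" for i in wild_parents.ids}
    group_of.update({i: "hatchery" for i in hatchery_parents.ids})
    motifs = np.array([l.motif_length for l in combined.loci], dtype=np.int64)

    per_group: dict[str, float] = {}
    confusion: dict[tuple[str, str], int] = {}
    n_half = max(config.n_pseudo_offspring // 2, 1)
    for group, table in (("wild", wild_parents), ("hatchery", hatchery_parents)):
        P = len(table)
        ia = rng.integers(0, P, size=n_half)
        ib = (ia + 1 + rng.integers(0, P - 1, size=n_half)) % P
        child = mendelian_offspring(table.alleles[ia], table.alleles[ib], rng)
        child = inject_offset_errors(
            child, motifs, config.error_rate_1off, config.error_rate_2off, rng
        )
        off_ids = [f"{group[0].upper()}O{k:05d}" for k in range(n_half)]
        offspring = GenotypeTable(combined.loci, off_ids, child)
        truth = pd.DataFrame(
            {
                "offspring_id": off_ids,
                "parent1": [table.ids[k] for k in ia],
                "parent2": [table.ids[k] for k in ib],
            }
        )
        swap = truth["parent1"] > truth["parent2"]
        truth.loc[swap, ["parent1", "parent2"]] = truth.loc[
            swap, ["parent2", "parent1"]
        ].to_numpy()
        result = allocate_all(offspring, combined, config)
        correct = score_against_truth(result, truth, set(combined.ids))
        per_group[group] = float(correct.mean())
        for _, row in result.loc[~correct.to_numpy()].iterrows():
            assigned_groups = {
                group_of[p]
                for p in (row["parent1"], row["parent2"])
                if p != UNSAMPLED
            }
            if not assigned_groups:
                assigned = "unallocated"
            elif len(assigned_groups) == 1:
                assigned = assigned_groups.pop()
            else:
                assigned = "mixed"
            confusion[(group, assigned)] = confusion.get((group, assigned), 0) + 1
    matrix = _confusion_frame(confusion)
    overall = float(np.mean(list(per_group.values())))
    return SimulationReport(overall, list(per_group.values()), matrix, per_group)
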