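"""Independent brute-force reference for offset-tolerant parental
allocation, written directly from the allocation rules with no shared code
with the engine: exhaustive enumeration over candidate pairs and per-locus
allele assignments."""

import itertools
import math

from spawnrs.allocation import UNSAMPLED


def _supply(parent, allele, motif, max_offset):
    d = min(
        round(abs(allele - parent[0]) / motif),
        round(abs(allele - parent[1]) / motif),
    )
    return d if d <= max_offset else math.inf


def _locus_key(off, pa, pb, motif, max_offset):
    """Best (n_bad_alleles, attributable cost) over the two assignments."""
    best = (3, math.inf)
    for x, y in ((off[0], off[1]), (off[1], off[0])):
        dx = _supply(pa, x, motif, max_offset)
        dy = _supply(pb, y, motif, max_offset)
        bad = (0 if math.isfinite(dx) else 1) + (0 if math.isfinite(dy) else 1)
        cost = (dx if math.isfinite(dx) else 0) + (dy if math.isfinite(dy) else 0)
        best = min(best, (bad, cost))
    return best


def brute_force_allocate(off, candidates, motifs, max_offset, budget, cap):
    """Reference allocation of one offspring.

    off: list of (a, b) per locus; candidates: dict id -> same structure.
    Returns (status, parent1, parent2, n_incompatible_loci, cost).
    """
    pair_scores = {}
    for ida, idb in itertools.combinations(sorted(candidates), 2):
        n_bad_loci = 0
        total = 0.0
        for l, motif in enumerate(motifs):
            bad, cost = _locus_key(
                off[l], candidates[ida][l], candidates[idb][l], motif, max_offset
            )
            n_bad_loci += bad > 0
            total += cost
        if n_bad_loci <= cap and total <= budget:
            pair_scores[(ida, idb)] = (n_bad_loci, total)
    if pair_scores:
        best = min(pair_scores.values())
        winners = [k for k, v in pair_scores.items() if v == best]
        if len(winners) == 1:
            (p1, p2) = winners[0]
            return ("pair", p1, p2, best[0], best[1])
        return ("ambiguous", UNSAMPLED, UNSAMPLED, 0, 0)

    single_scores = {}
    for idc, geno in candidates.items():
        total = 0.0
        for l, motif in enumerate(motifs):
            d = min(
                _supply(geno[l], off[l][0], motif, max_offset),
                _supply(geno[l], off[l][1], motif, max_offset),
            )
            total += d
        if math.isfinite(total) and total <= budget:
            single_scores[idc] = total
    if single_scores:
        best = min(single_scores.values())
        winners = [k for k, v in single_scores.items() if v == best]
        if len(winners) == 1:
            return ("single", winners[0], UNSAMPLED, 0, best)
        return ("ambiguous", UNSAMPLED, UNSAMPLED, 0, 0)
    return ("none", UNSAMPLED, UNSAMPLED, 0, 0)


def random_instance(rng, max_candidates=6, max_loci=3):
    """A random small allocation instance with frequent near-ties."""
    n_cand = int(rng.integers(2, max_candidates + 1))
    n_loci = int(rng.integers(1, max_loci + 1))
    motifs = [int(rng.choice([2, 4]))] * n_loci
    max_offset = int(rng.integers(0, 3))
    budget = int(rng.integers(0, 4))
    cap = int(rng.integers(0, 2))

    def genotype():
        return [
            tuple(sorted(100 + motifs[l] * rng.integers(0, 6, size=2)))
            for l in range(n_loci)
        ]

    off = genotype()
    candidates = {f"c{k}": genotype() for k in range(n_cand)}
    return off, candidates, motifs, max_offset, budget, cap
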