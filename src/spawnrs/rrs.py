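"""Reproductive success, RRS ratios with bootstrap intervals, and 2x2
contingency comparisons.

Reproductive success (RS) of a spawner is the number of sampled juveniles
allocated to it; each offspring contributes up to two offspring-parent
dyads, and slots attributed to uncollected parents contribute to nobody.
Relative reproductive success (RRS) of a focal group against a reference
group is the ratio of group mean RS, with percentile bootstrap confidence
intervals obtained by resampling spawners with replacement within each
group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allocation import UNSAMPLED

logger = logging.getLogger(__name__)


def reproductive_success(
    allocation: pd.DataFrame,
    spawners: pd.DataFrame,
) -> pd.DataFrame:
    """Per-spawner offspring counts from an allocation result.

    ``spawners`` is a metadata table with at least an ``id`` column (plus
    any covariates: year, origin, sex, sea_winters, ...); the returned
    table is ``spawners`` with an ``rs`` count column appended.  Every
    collected parent named by the allocation must appear in ``spawners``.
    """
    counts: dict[str, int] = {}
    for col in ("parent1", "parent2"):
        for pid in allocation[col]:
            if pid != UNSAMPLED:
                counts[pid] = counts.get(pid, 0) + 1
    known = set(spawners["id"].astype(str))
    orphans = sorted(set(counts) - known)
    if orphans:
        raise ValueError(
            f"allocation references spawners absent from metadata: {orphans[:5]}"
        )
    out = spawners.copy()
    out["rs"] = out["id"].astype(str).map(counts).fillna(0).astype(int)
    return out


def rrs(focal: np.ndarray, reference: np.ndarray) -> float:
    """Ratio of mean RS, focal over reference; NaN if the reference mean
    is zero (flagged with a warning)."""
    focal = np.asarray(focal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ref_mean = reference.mean()
    if ref_mean == 0:
        warnings.warn("reference group mean RS is zero; RRS undefined")
        return float("nan")
    return float(focal.mean() / ref_mean)


@dataclass
class RRSEstimate:
    """RRS point estimate with a percentile bootstrap interval."""

    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    n_focal: int
    n_reference: int


def bootstrap_rrs(
    focal: np.ndarray,
    reference: np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> RRSEstimate:
    """Percentile bootstrap CI for the ratio of group mean RS.

    Individuals are resampled with replacement within each group
    independently.  Resamples whose reference mean is zero are redrawn
    (logged); a group of size 1 yields a degenerate interval.
    """
    focal = np.asarray(focal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if focal.size == 0 or reference.size == 0:
        raise ValueError("both groups must be non-empty")
    if focal.size == 1 or reference.size == 1:
        warnings.warn("bootstrap over a single-individual group is degenerate")
    point = rrs(focal, reference)
    rng = np.random.default_rng(seed)
    nf, nr = focal.size, reference.size
    fmeans = focal[rng.integers(0, nf, size=(n_boot, nf))].mean(axis=1)
    rmeans = reference[rng.integers(0, nr, size=(n_boot, nr))].mean(axis=1)
    zero = rmeans == 0
    n_redrawn = 0
    while zero.any():
        k = int(zero.sum())
        n_redrawn += k
        rmeans[zero] = reference[rng.integers(0, nr, size=(k, nr))].mean(axis=1)
        zero = rmeans == 0
        if reference.max() == 0:
            raise ValueError("reference group is all zero; RRS undefined")
    if n_redrawn:
        logger.info("bootstrap_rrs: redrew %d resamples with zero reference mean",
                    n_redrawn)
    ratios = fmeans / rmeans
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    return RRSEstimate(point, float(lo), float(hi), n_boot, seed, nf, nr)


def weighted_geometric_mean(ratios, weights) -> float:
    """exp(sum w_i ln r_i / sum w_i); ratios must be positive."""
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (r <= 0).any():
        raise ValueError("ratios must be strictly positive")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    return float(np.exp(np.sum(w * np.log(r)) / w.sum()))


def two_by_two_chisq(table) -> dict:
    """Pearson chi-square on a 2x2 table, without continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def representation_vs_contribution(
    n_hatchery_spawners: int,
    n_wild_spawners: int,
    n_hatchery_dyads: int,
    n_wild_dyads: int,
) -> dict:
    """Compare the hatchery share among known-origin spawners
    (representation) with its share among collected-parent dyads
    (contribution).

    Equal shares mean hatchery fish reproduce in proportion to their
    abundance; a contribution below representation indicates reduced
    relative reproductive output.  Tested by Pearson chi-square on the two
    count pairs.
    """
    n_dyads = n_hatchery_dyads + n_wild_dyads
    if n_dyads == 0:
        raise ValueError("no offspring-parent dyads")
    test = two_by_two_chisq(
        [[n_hatchery_spawners, n_wild_spawners], [n_hatchery_dyads, n_wild_dyads]]
    )
    rep = n_hatchery_spawners / (n_hatchery_spawners + n_wild_spawners)
    contrib = n_hatchery_dyads / n_dyads
    return {
        "representation": float(rep),
        "contribution": float(contrib),
        "n_spawners": int(n_hatchery_spawners + n_wild_spawners),
        "n_dyads": int(n_dyads),
        **test,
    }


def dyad_origin_counts(
    allocation: pd.DataFrame,
    origin_by_id: pd.Series | dict,
) -> tuple[int, int]:
    """Count collected-parent dyads with hatchery-born vs wild-born parents.

    Dyads whose parent has unknown origin are excluded.  ``origin_by_id``
    maps spawner id to one of wild / fry_stocked / smolt_stocked / unknown.
    """
    origin_by_id = dict(origin_by_id)
    n_hatch = n_wild = 0
    for col in ("parent1", "parent2"):
        for pid in allocation[col]:
            if pid == UNSAMPLED:
                continue
            origin = origin_by_id.get(pid, "unknown")
            if origin in ("fry_stocked", "smolt_stocked"):
                n_hatch += 1
            elif origin == "wild":
                n_wild += 1
    return n_hatch, n_wild


def rrs_by_group(
    rs_table: pd.DataFrame,
    group_col: str = "origin",
    focal: str = "hatchery",
    reference: str = "wild",
    n_boot: int = 10000,
    seed: int | None = None,
) -> RRSEstimate:
    """Bootstrap RRS between two levels of a grouping column of an RS table.

    The pseudo-level ``"hatchery"`` pools fry_stocked and smolt_stocked.
    """
    def values(level: str) -> np.ndarray:
        if level == "hatchery" and group_col == "origin":
            mask = rs_table[group_col].isin(["fry_stocked", "smolt_stocked"])
        else:
            mask = rs_table[group_col] == level
        return rs_table.loc[mask, "rs"].to_numpy(dtype=float)

    return bootstrap_rrs(values(focal), values(reference), n_boot=n_boot, seed=seed)
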