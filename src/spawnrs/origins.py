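"""Classification of returning adults as wild-born, fry-stocked or
smolt-stocked.

Smolt-stocked fish are recognised from their scale growth pattern (consumed
here as a boolean flag).  Fry-stocked fish carry no scale signature and are
recognised genetically: an adult is called fry-stocked when it is allocated
to a pair of hatchery broodstock parents with at most one incompatible
allele.  "At most one incompatible allele" is counted across all loci: at
most one of the adult's alleles may be unattributable to the allocated pair
within the offset tolerance (a single incompatible locus can contribute one
or two such alleles), a stricter reading than a locus-level cap.

Adults born before the broodstock pool was genotyped can only land in the
wild class, so per-year summaries should be read with a coverage caveat for
early years.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

ORIGINS = ("wild", "fry_stocked", "smolt_stocked", "unknown")


@dataclass
class OriginCall:
    """Origin of one returning adult, with the evidence used."""

    individual_id: str
    origin: str
    scale_flag_used: bool
    broodstock_status: str  # allocation status vs the broodstock pool, or "n/a"
    n_incompatible_alleles: int | None


def classify_spawner(
    individual_id: str,
    scale_smolt_flag: bool | None,
    broodstock_allocation: pd.Series | dict | None,
    genotype_complete: bool = True,
    max_incompatible_alleles: int = 1,
) -> OriginCall:
    """Apply the origin-precedence rules to one adult.

    Precedence: (1) a true scale flag calls smolt_stocked; (2) otherwise an
    allocation to two broodstock parents with at most
    ``max_incompatible_alleles`` incompatible alleles calls fry_stocked;
    (3) otherwise, if the scale flag is known and the genotype complete,
    wild; (4) otherwise unknown.
    """
    alloc = broodstock_allocation
    status = str(alloc["status"]) if alloc is not None else "n/a"
    n_bad = int(alloc["n_incompatible_alleles"]) if alloc is not None else None

    if scale_smolt_flag is True:
        return OriginCall(individual_id, "smolt_stocked", True, status, n_bad)
    if (
        alloc is not None
        and status == "pair"
        and n_bad is not None
        and n_bad <= max_incompatible_alleles
    ):
        return OriginCall(individual_id, "fry_stocked", False, status, n_bad)
    if scale_smolt_flag is not None and genotype_complete:
        return OriginCall(individual_id, "wild", False, status, n_bad)
    return OriginCall(individual_id, "unknown", False, status, n_bad)


def classify_all(
    adults: pd.DataFrame,
    broodstock_allocations: pd.DataFrame | None = None,
    max_incompatible_alleles: int = 1,
) -> pd.DataFrame:
    """Classify every adult in a metadata table.

    ``adults`` needs columns ``id``, ``scale_smolt_flag`` (True/False/NA)
    and optionally ``genotype_complete``; ``broodstock_allocations`` is an
    allocation result table (one row per adult treated as offspring of the
    broodstock pool).  Returns one row per adult with the origin call and
    evidence columns.
    """
    alloc_by_id: dict[str, pd.Series] = {}
    if broodstock_allocations is not None:
        for _, row in broodstock_allocations.iterrows():
            alloc_by_id[str(row["offspring_id"])] = row
    rows = []
    for _, adult in adults.iterrows():
        flag = adult["scale_smolt_flag"]
        flag = None if pd.isna(flag) else bool(flag)
        complete = bool(adult.get("genotype_complete", True))
        call = classify_spawner(
            str(adult["id"]),
            flag,
            alloc_by_id.get(str(adult["id"])),
            genotype_complete=complete,
            max_incompatible_alleles=max_incompatible_alleles,
        )
        rows.append(
            {
                "id": call.individual_id,
                "year": adult.get("year"),
                "origin": call.origin,
                "scale_flag_used": call.scale_flag_used,
                "broodstock_status": call.broodstock_status,
                "n_incompatible_alleles": call.n_incompatible_alleles,
            }
        )
    return pd.DataFrame(rows)


def origin_summary(calls: pd.DataFrame, years: list | None = None) -> pd.DataFrame:
    """Per-year breakdown of origin calls (hatchery = fry + smolt stocked).

    Returns rows wild / hatchery / fry_stocked / smolt_stocked / known /
    unknown with one column per year plus a total column.
    """
    if years is None:
        years = sorted(y for y in calls["year"].dropna().unique())
    rows = {
        name: {}
        for name in ("wild", "hatchery", "fry_stocked", "smolt_stocked", "known", "unknown")
    }
    for year in years:
        sub = calls[calls["year"] == year] if years else calls
        counts = sub["origin"].value_counts()
        wild = int(counts.get("wild", 0))
        fry = int(counts.get("fry_stocked", 0))
        smolt = int(counts.get("smolt_stocked", 0))
        unknown = int(counts.get("unknown", 0))
        rows["wild"][year] = wild
        rows["fry_stocked"][year] = fry
        rows["smolt_stocked"][year] = smolt
        rows["hatchery"][year] = fry + smolt
        rows["known"][year] = wild + fry + smolt
        rows["unknown"][year] = unknown
    out = pd.DataFrame(rows).T
    out = out.reindex(columns=years)
    out["total"] = out.sum(axis=1)
    return out.astype(int)
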