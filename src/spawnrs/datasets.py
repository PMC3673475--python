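"""Published summary tables from a three-year supportive-breeding study.

These are the printed count and mean-RS tables of a monitoring program on
a small anadromous Atlantic salmon population supplemented from a ~20-
breeder hatchery broodstock (returning adults 2002-2004, fry cohorts
2003-2005).  The raw genotypes were never deposited, so these summaries
are consumed as data: they drive the arithmetic cross-checks (RRS ratios,
representation percentages, analysis of deviance on printed deviances) and
anchor the simulator's default sample sizes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

YEARS = (2002, 2003, 2004)


def spawner_count_table() -> pd.DataFrame:
    """Adult and juvenile counts per spawning year (rows x years + total)."""
    data = {
        "transported": (153, 324, 399),
        "used_for_assignment": (136, 287, 362),
        "known_origin": (135, 253, 348),
        "wild": (120, 167, 206),
        "hatchery": (15, 86, 142),
        "smolt_stocked": (14, 70, 51),
        "fry_stocked": (1, 16, 91),
        "ssw": (108, 204, 204),
        "msw": (28, 73, 154),
        "fry_assigned": (226, 421, 494),
    }
    df = pd.DataFrame(data, index=list(YEARS)).T
    df["total"] = df.sum(axis=1)
    return df


def mean_rs_table() -> pd.DataFrame:
    """Mean reproductive success by origin, year and category.

    Index: (origin, year) with year ``"pooled"`` for all years combined;
    columns are the reporting categories (sea-winter class, sex, stage
    stocked, and the overall mean).  ``None`` marks empty categories.
    """
    cols = ["ssw", "msw", "female", "ind", "male", "fry", "smolt", "total"]
    rows = {
        ("wild", 2002): [1.28, 5.69, 3.82, 2.23, 1.66, None, None, 2.13],
        ("wild", 2003): [1.12, 5.08, 4.41, 4.48, 1.54, None, None, 2.58],
        ("wild", 2004): [1.02, 3.41, 2.26, 2.20, 1.42, None, None, 2.26],
        ("wild", "pooled"): [1.14, 4.25, 3.49, 3.00, 1.53, None, None, 2.34],
        ("hatchery", 2002): [0.71, None, None, 0.80, 0.67, None, 0.67, 0.63],
        ("hatchery", 2003): [0.81, 7.20, 4.63, 0.81, 0.83, 1.00, 1.19, 1.15],
        ("hatchery", 2004): [0.94, 2.43, 1.30, 1.93, 1.11, 1.81, 0.77, 1.44],
        ("hatchery", "pooled"): [0.87, 2.77, 2.10, 1.61, 0.95, 1.66, 0.98, 1.28],
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["origin", "year"])
    return df


def model_deviance_table() -> pd.DataFrame:
    """Printed deviances and residual df of the three RS-count models."""
    return pd.DataFrame(
        {
            "model": ["model1", "model2", "model3"],
            "deviance": [1980.69, 2009.9, 1995.47],
            "df": [527, 532, 531],
        }
    ).set_index("model")


def make_reference_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the printed tables as CSV fixtures and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("spawner_counts", spawner_count_table()),
        ("mean_rs", mean_rs_table()),
        ("model_deviances", model_deviance_table()),
    ):
        path = outdir / f"{name}.csv"
        df.to_csv(path)
        paths[name] = path
    return paths
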