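"""Multilocus microsatellite genotype tables and summary statistics.

Genotypes are unordered pairs of integer allele sizes (base pairs) at a set
of tandem-repeat loci.  Scoring-error distances used elsewhere in the
package are expressed in repeat units, i.e. size difference divided by the
locus motif length, so every locus carries its motif length with it.

Missing alleles are encoded as :data:`MISSING` (-1) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel allele size for an unscored allele.
MISSING: int = -1


@dataclass(frozen=True)
class LocusDef:
    """Definition of one microsatellite locus.

    Parameters
    ----------
    name:
        Locus identifier, e.g. ``"SsaD71"``.
    motif_length:
        Length of the tandem-repeat motif in base pairs (>= 1); offset
        distances are measured in units of this length.
    genepop_offset:
        Size in base pairs corresponding to GenePop allele code 0.  Allele
        sizes are written to GenePop as ``size - genepop_offset`` and
        reconstructed on read as ``code + genepop_offset``.
    """

    name: str
    motif_length: int = 4
    genepop_offset: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1 for locus {self.name!r}")


class GenotypeTable:
    """Per-individual allele pairs over an ordered list of loci.

    Internally stored as an ``(n_individuals, n_loci, 2)`` integer array with
    :data:`MISSING` for unscored alleles.  Allele pairs are unordered; the
    stored order is canonicalised (sorted, missing last) so that equality and
    round-trips are well defined.
    """

    def __init__(
        self,
        loci: Sequence[LocusDef],
        ids: Sequence[str],
        alleles: np.ndarray,
        pools: Sequence[str] | None = None,
    ) -> None:
        ids = list(ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        alleles = np.asarray(alleles, dtype=np.int64)
        if alleles.shape != (len(ids), len(loci), 2):
            raise ValueError(
                f"allele array shape {alleles.shape} does not match "
                f"({len(ids)}, {len(loci)}, 2)"
            )
        self.loci: list[LocusDef] = list(loci)
        self.ids: list[str] = ids
        self.alleles = _canonicalise(alleles)
        self.pools: list[str] | None = list(pools) if pools is not None else None
        self._id_index = {ind: k for k, ind in enumerate(ids)}
        self._check_motif_congruence()

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and [l.name for l in self.loci] == [l.name for l in other.loci]
            and np.array_equal(self.alleles, other.alleles)
        )

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus_index(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown locus {name!r}") from None

    def row(self, individual_id: str) -> np.ndarray:
        """Return the ``(n_loci, 2)`` allele array for one individual."""
        return self.alleles[self._id_index[individual_id]]

    def complete_mask(self) -> np.ndarray:
        """Boolean mask of individuals with no MISSING allele at any locus."""
        return (self.alleles != MISSING).all(axis=(1, 2))

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeTable":
        idx = [self._id_index[i] for i in ids]
        pools = [self.pools[k] for k in idx] if self.pools is not None else None
        return GenotypeTable(
            self.loci, [self.ids[k] for k in idx], self.alleles[idx], pools
        )

    def subset_loci(self, locus_names: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_index(n) for n in locus_names]
        return GenotypeTable(
            [self.loci[k] for k in idx], self.ids, self.alleles[:, idx, :], self.pools
        )

    def drop_incomplete(self) -> "GenotypeTable":
        """Drop individuals with any MISSING allele (complete-genotype rule)."""
        keep = self.complete_mask()
        ids = [i for i, k in zip(self.ids, keep) if k]
        pools = (
            [p for p, k in zip(self.pools, keep) if k]
            if self.pools is not None
            else None
        )
        return GenotypeTable(self.loci, ids, self.alleles[keep], pools)

    # -- dataframe / file I/O ----------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """CSV-schema dataframe: id, pool, then ``<locus>_a1``/``<locus>_a2``."""
        data: dict[str, object] = {"id": self.ids}
        data["pool"] = self.pools if self.pools is not None else [""] * len(self)
        for j, locus in enumerate(self.loci):
            for a in (0, 1):
                col = self.alleles[:, j, a].astype(object)
                data[f"{locus.name}_a{a + 1}"] = [
                    "" if v == MISSING else int(v) for v in col
                ]
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_genepop(self, path: str | Path, title: str = "spawnrs export") -> None:
        """Write GenePop with 3-digit allele codes (``000`` = missing)."""
        lines = [title]
        lines.extend(l.name for l in self.loci)
        lines.append("POP")
        for k, ind in enumerate(self.ids):
            codes = []
            for j, locus in enumerate(self.loci):
                pair = []
                for a in (0, 1):
                    size = self.alleles[k, j, a]
                    if size == MISSING:
                        pair.append("000")
                    else:
                        code = int(size) - locus.genepop_offset
                        if not 1 <= code <= 999:
                            raise ValueError(
                                f"allele {size} at {locus.name} not encodable as a "
                                f"3-digit GenePop code with offset {locus.genepop_offset}"
                            )
                        pair.append(f"{code:03d}")
                codes.append("".join(pair))
            lines.append(f"{ind} ,  " + " ".join(codes))
        Path(path).write_text("\n".join(lines) + "\n")

    # -- internals ----------------------------------------------------------

    def _check_motif_congruence(self) -> None:
        for j, locus in enumerate(self.loci):
            obs = self.alleles[:, j, :]
            obs = obs[obs != MISSING]
            if obs.size and len(set(obs % locus.motif_length)) > 1:
                warnings.warn(
                    f"locus {locus.name}: allele sizes are not all congruent "
                    f"modulo motif length {locus.motif_length} (off-ladder alleles)",
                    stacklevel=3,
                )
                return


def _canonicalise(alleles: np.ndarray) -> np.ndarray:
    """Sort each pair ascending with MISSING last; pairs are unordered."""
    out = np.sort(alleles, axis=2)
    # move MISSING (-1) after the scored allele so (a, MISSING) is canonical
    half = (out[:, :, 0] == MISSING) & (out[:, :, 1] != MISSING)
    out[half] = out[half][:, ::-1]
    return out


# ---------------------------------------------------------------------------
# Reading


def read_genotypes(
    path: str | Path,
    format: str,
    locus_defs: Sequence[LocusDef],
) -> GenotypeTable:
    """Read a genotype table from ``csv`` or ``genepop`` format.

    The CSV schema is: columns ``id``, ``pool``, then for every locus ``L``
    the columns ``L_a1``/``L_a2`` holding integer allele sizes, with an empty
    cell meaning missing.  GenePop allele codes of 2 or 3 digits are
    accepted; ``00``/``000`` (and the 6-digit ``000000``) mean missing, and
    sizes are reconstructed as ``code + genepop_offset`` per locus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path, locus_defs)
    if format == "genepop":
        return _read_genepop(path, locus_defs)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'genepop'")


def _read_csv(path: Path, locus_defs: Sequence[LocusDef]) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"id": str, "pool": str}, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'id'")
    for locus in locus_defs:
        for a in (1, 2):
            if f"{locus.name}_a{a}" not in df.columns:
                raise ValueError(f"{path}: missing column {locus.name}_a{a}")
    n, L = len(df), len(locus_defs)
    alleles = np.full((n, L, 2), MISSING, dtype=np.int64)
    for j, locus in enumerate(locus_defs):
        for a in (0, 1):
            col = df[f"{locus.name}_a{a + 1}"].astype(str).str.strip()
            scored = col != ""
            try:
                alleles[scored.to_numpy(), j, a] = col[scored].astype(float).astype(int)
            except ValueError as exc:
                raise ValueError(f"{path}: bad allele value at {locus.name}: {exc}")
    pools = df["pool"].tolist() if "pool" in df.columns else None
    return GenotypeTable(locus_defs, df["id"].tolist(), alleles, pools)


def _read_genepop(path: Path, locus_defs: Sequence[LocusDef]) -> GenotypeTable:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: truncated GenePop file")
    # locus names: one per line, or comma-separated on one line, until POP
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: no POP line found")
    expected = [l.name for l in locus_defs]
    if locus_names != expected:
        raise ValueError(
            f"{path}: locus names {locus_names} do not match declared {expected}"
        )
    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for lineno, line in enumerate(lines[i + 1 :], start=i + 2):
        line = line.strip()
        if not line:
            continue
        if line.upper() == "POP":
            continue  # multiple pops are concatenated
        if "," not in line:
            raise ValueError(f"{path}:{lineno}: expected 'id , genotypes'")
        ind, geno = line.split(",", 1)
        codes = geno.split()
        if len(codes) != len(locus_defs):
            raise ValueError(
                f"{path}:{lineno}: expected {len(locus_defs)} loci, got {len(codes)}"
            )
        pairs = []
        for code, locus in zip(codes, locus_defs):
            if len(code) not in (4, 6) or not code.isdigit():
                raise ValueError(f"{path}:{lineno}: malformed allele code {code!r}")
            w = len(code) // 2
            a, b = int(code[:w]), int(code[w:])
            pairs.append(
                (
                    MISSING if a == 0 else a + locus.genepop_offset,
                    MISSING if b == 0 else b + locus.genepop_offset,
                )
            )
        ids.append(ind.strip())
        rows.append(pairs)
    alleles = np.array(rows, dtype=np.int64).reshape(len(ids), len(locus_defs), 2)
    return GenotypeTable(locus_defs, ids, alleles)


def write_genotypes(table: GenotypeTable, path: str | Path, format: str) -> None:
    if format == "csv":
        table.write_csv(path)
    elif format == "genepop":
        table.write_genepop(path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Summary statistics


class AlleleFrequencyTable:
    """Per-locus relative allele frequencies (support = observed alleles)."""

    def __init__(self, loci: Sequence[LocusDef], freqs: Mapping[str, dict[int, float]]):
        self.loci = list(loci)
        self.freqs = {name: dict(f) for name, f in freqs.items()}
        for name, f in self.freqs.items():
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {name} sum to {total}, not 1")

    def __getitem__(self, locus_name: str) -> dict[int, float]:
        return self.freqs[locus_name]

    def alleles_and_probs(self, locus_name: str) -> tuple[np.ndarray, np.ndarray]:
        f = self.freqs[locus_name]
        alleles = np.array(sorted(f), dtype=np.int64)
        probs = np.array([f[a] for a in alleles])
        return alleles, probs

    def sample_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``(n, n_loci, 2)`` genotypes by i.i.d. allele sampling."""
        out = np.empty((n, len(self.loci), 2), dtype=np.int64)
        for j, locus in enumerate(self.loci):
            alleles, probs = self.alleles_and_probs(locus.name)
            out[:, j, :] = rng.choice(alleles, size=(n, 2), p=probs)
        return out


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencyTable:
    """Empirical allele frequencies per locus over non-missing alleles."""
    if len(table) == 0:
        raise ValueError("empty genotype table")
    freqs: dict[str, dict[int, float]] = {}
    for j, locus in enumerate(table.loci):
        obs = table.alleles[:, j, :].ravel()
        obs = obs[obs != MISSING]
        if obs.size == 0:
            raise ValueError(f"locus {locus.name}: all genotypes missing")
        values, counts = np.unique(obs, return_counts=True)
        freqs[locus.name] = {
            int(v): float(c) / obs.size for v, c in zip(values, counts)
        }
    return AlleleFrequencyTable(table.loci, freqs)


def heterozygosity(table: GenotypeTable, locus: str, kind: str = "observed") -> float:
    """Observed or expected (gene diversity, 1 - sum p_i^2) heterozygosity."""
    j = table.locus_index(locus)
    pairs = table.alleles[:, j, :]
    scored = (pairs != MISSING).all(axis=1)
    if not scored.any():
        raise ValueError(f"locus {locus}: no complete genotypes")
    if kind == "observed":
        het = pairs[scored, 0] != pairs[scored, 1]
        return float(het.mean())
    if kind == "expected":
        obs = pairs[scored].ravel()
        _, counts = np.unique(obs, return_counts=True)
        p = counts / counts.sum()
        return float(1.0 - np.sum(p**2))
    raise ValueError(f"unknown kind {kind!r}; expected 'observed' or 'expected'")


def allele_count_summary(table: GenotypeTable) -> pd.DataFrame:
    """Distinct non-missing allele count per locus, with a summary row.

    Returns a dataframe with columns ``locus`` and ``n_alleles``; the
    min/median/max over loci are available via ``df['n_alleles'].describe()``
    or the attached ``df.attrs['summary']`` dict.
    """
    rows = []
    for j, locus in enumerate(table.loci):
        obs = table.alleles[:, j, :].ravel()
        obs = obs[obs != MISSING]
        if obs.size == 0:
            warnings.warn(f"locus {locus.name}: no scored alleles, excluded")
            continue
        rows.append({"locus": locus.name, "n_alleles": int(len(np.unique(obs)))})
    df = pd.DataFrame(rows, columns=["locus", "n_alleles"])
    if len(df):
        df.attrs["summary"] = {
            "min": int(df["n_alleles"].min()),
            "median": float(df["n_alleles"].median()),
            "max": int(df["n_alleles"].max()),
        }
    else:
        df.attrs["summary"] = {}
    return df
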