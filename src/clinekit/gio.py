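"""Genotype and metadata I/O.

Supported formats: Genepop (2- or 3-digit allele codes, diploid or haploid),
wide CSV genotype tables (one column per locus, alleles slash-separated),
site tables as CSV, and per-site haplotype count tables.

Internal representation
-----------------------
:class:`GenotypeMatrix` stores alleles as an ``(n_individuals, n_loci, 2)``
integer array of positive allele codes with 0 as the missing sentinel.
Haploid loci use only the first slot. For biallelic loci the "reference"
allele is the lexicographically (numerically) smallest observed code; the
biological polarity (northern vs southern) is assigned downstream from
lineage frequencies, never at parse time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0


class GenepopParseError(ValueError):
    """Raised for malformed Genepop input (names the offending line)."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele table with per-locus ploidy.

    Parameters
    ----------
    individuals : pandas.DataFrame
        One row per individual, columns ``id``, ``site`` and optionally
        ``year``, ``stage``. IDs must be unique.
    loci : pandas.DataFrame
        One row per locus, columns ``name``, ``kind`` (``snp`` |
        ``microsat`` | ``mtdna``) and ``ploidy`` (1 or 2).
    alleles : numpy.ndarray
        ``(n, L, 2)`` integer array; 0 denotes a missing copy.
    """

    individuals: pd.DataFrame
    loci: pd.DataFrame
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)
        if self.individuals["id"].duplicated().any():
            dupes = self.individuals["id"][self.individuals["id"].duplicated()]
            raise ValueError(f"duplicate individual IDs: {sorted(set(dupes))}")
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.shape != (self.n_individuals, self.n_loci, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"({self.n_individuals}, {self.n_loci}, 2)"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    # -- missingness ---------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean: genotype missing (any required copy absent)."""
        ploidy = self.loci["ploidy"].to_numpy()
        miss = self.alleles[:, :, 0] == MISSING
        dip = ploidy == 2
        miss[:, dip] |= self.alleles[:, dip, 1] == MISSING
        return miss

    def failed_loci_per_individual(self) -> np.ndarray:
        return self.missing_mask().sum(axis=1)

    # -- views ---------------------------------------------------------
    def ref_allele_codes(self) -> np.ndarray:
        """Smallest positive allele code per locus (0 if fully untyped)."""
        a = self.alleles.astype(float)
        a[a == MISSING] = np.inf
        codes = np.min(a, axis=(0, 2))
        codes[~np.isfinite(codes)] = 0
        return codes.astype(np.int32)

    def ref_counts(self) -> np.ndarray:
        """(n, L) float count of the reference allele; NaN where missing.

        Intended for biallelic diploid loci (values 0/1/2) but defined for
        haploid loci as well (values 0/1).
        """
        ref = self.ref_allele_codes()
        counts = (self.alleles == ref[None, :, None]).sum(axis=2).astype(float)
        counts[self.missing_mask()] = np.nan
        return counts

    def allele_counts_by_site(self) -> dict[str, dict[str, pd.Series]]:
        """Per site, per locus: Series of allele code -> copy count."""
        out: dict[str, dict[str, pd.Series]] = {}
        sites = self.individuals["site"].to_numpy()
        for site in pd.unique(sites):
            rows = np.flatnonzero(sites == site)
            per_locus = {}
            for j, name in enumerate(self.loci["name"]):
                ploidy = int(self.loci["ploidy"].iloc[j])
                copies = self.alleles[rows, j, :ploidy].ravel()
                copies = copies[copies != MISSING]
                per_locus[name] = pd.Series(copies).value_counts().sort_index()
            out[site] = per_locus
        return out

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.individuals.iloc[keep].reset_index(drop=True),
            self.loci.copy(),
            self.alleles[keep],
        )

    def subset_sites(self, sites) -> "GenotypeMatrix":
        keep = np.flatnonzero(self.individuals["site"].isin(list(sites)))
        return GenotypeMatrix(
            self.individuals.iloc[keep].reset_index(drop=True),
            self.loci.copy(),
            self.alleles[keep],
        )

    def merge(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Concatenate two matrices over disjoint individuals, same loci."""
        if list(self.loci["name"]) != list(other.loci["name"]):
            raise ValueError("cannot merge: locus sets differ")
        inds = pd.concat([self.individuals, other.individuals], ignore_index=True)
        return GenotypeMatrix(inds, self.loci.copy(), np.vstack([self.alleles, other.alleles]))


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _site_from_label(label: str, pop_index: int) -> str:
    if "_" in label:
        return label.rsplit("_", 1)[0]
    return f"POP{pop_index + 1}"


def read_genepop(path) -> GenotypeMatrix:
    """Parse a Genepop file (title, locus block, POP-delimited samples).

    ``00``/``000`` allele codes map to missing. Site codes are parsed from
    individual labels (text before the final underscore), falling back to
    ``POP<k>`` for the k-th population block.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GenepopParseError("empty file")
    body = lines[1:]  # title line ignored
    # locus block: names until first POP line; may be comma-separated
    loci_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i].strip()
        if chunk:
            loci_names.extend([t.strip() for t in chunk.split(",") if t.strip()])
        i += 1
    if i == len(body):
        raise GenepopParseError("no POP line found")
    n_loci = len(loci_names)
    ids, sites_col, rows = [], [], []
    widths: set[int] = set()
    ploidy = np.zeros(n_loci, dtype=int)
    pop_index = -1
    for lineno, raw in enumerate(body[i:], start=i + 2):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_index += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"line {lineno}: expected 'label , genotypes'")
        label, geno = line.split(",", 1)
        label = label.strip()
        entries = geno.split()
        if len(entries) != n_loci:
            raise GenepopParseError(
                f"line {lineno}: {len(entries)} genotype entries for {n_loci} loci"
            )
        row = np.zeros((n_loci, 2), dtype=np.int32)
        for j, ent in enumerate(entries):
            if not re.fullmatch(r"\d+", ent):
                raise GenepopParseError(f"line {lineno}: bad genotype entry {ent!r}")
            if len(ent) in (4, 6):
                w = len(ent) // 2
                row[j, 0] = int(ent[:w])
                row[j, 1] = int(ent[w:])
                ploidy[j] = 2
            elif len(ent) in (2, 3):
                row[j, 0] = int(ent)
                ploidy[j] = max(ploidy[j], 1)
            else:
                raise GenepopParseError(
                    f"line {lineno}: unknown allele-code width in entry {ent!r}"
                )
            widths.add(len(ent) // (2 if len(ent) in (4, 6) else 1))
        ids.append(label)
        sites_col.append(_site_from_label(label, pop_index))
        rows.append(row)
    if not rows:
        raise GenepopParseError("no individuals found")
    ploidy[ploidy == 0] = 2
    max_code = max(int(np.max(r)) for r in rows)
    kind = "microsat" if (3 in widths or max_code > 9) else "snp"
    loci = pd.DataFrame(
        {"name": loci_names, "kind": [kind if p == 2 else "mtdna" for p in ploidy], "ploidy": ploidy}
    )
    inds = pd.DataFrame({"id": ids, "site": sites_col})
    return GenotypeMatrix(inds, loci, np.stack(rows))


def write_genepop(matrix: GenotypeMatrix, path, title: str = "clinekit export") -> str:
    """Write Genepop; digit width is 3 if any allele code exceeds 9."""
    # 2-digit codes for small SNP-style alleles; 3-digit once codes exceed 9
    # (microsatellite fragment sizes)
    width = 3 if matrix.alleles.max() > 9 else 2
    lines = [title]
    lines.extend(matrix.loci["name"])
    ploidy = matrix.loci["ploidy"].to_numpy()
    for site in pd.unique(matrix.individuals["site"]):
        lines.append("POP")
        for i in np.flatnonzero((matrix.individuals["site"] == site).to_numpy()):
            parts = []
            for j in range(matrix.n_loci):
                a, b = matrix.alleles[i, j]
                if ploidy[j] == 2:
                    parts.append(f"{a:0{width}d}{b:0{width}d}")
                else:
                    parts.append(f"{a:0{width}d}")
            lines.append(f"{matrix.individuals['id'].iloc[i]} ,  " + " ".join(parts))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# Wide CSV
# ---------------------------------------------------------------------------

_META_COLS = ["id", "site", "year", "stage"]


def write_wide_csv(matrix: GenotypeMatrix, path) -> str:
    """One column per locus; alleles slash-separated; empty cell = missing."""
    df = matrix.individuals.copy()
    ploidy = matrix.loci["ploidy"].to_numpy()
    for j, name in enumerate(matrix.loci["name"]):
        col = []
        for i in range(matrix.n_individuals):
            a, b = matrix.alleles[i, j]
            if ploidy[j] == 1:
                col.append("" if a == MISSING else str(a))
            else:
                col.append("" if (a == MISSING or b == MISSING) else f"{a}/{b}")
        df[name] = col
    df.to_csv(path, index=False)
    return str(path)


def read_wide_csv(path, loci_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta = [c for c in _META_COLS if c in df.columns]
    locus_cols = [c for c in df.columns if c not in meta]
    n, L = len(df), len(locus_cols)
    alleles = np.zeros((n, L, 2), dtype=np.int32)
    ploidy = np.ones(L, dtype=int)
    for j, c in enumerate(locus_cols):
        for i, cell in enumerate(df[c]):
            if cell == "":
                continue
            if "/" in cell:
                a, b = cell.split("/")
                alleles[i, j] = (int(a), int(b))
                ploidy[j] = 2
            else:
                alleles[i, j, 0] = int(cell)
    if loci_meta is not None:
        loci = loci_meta.reset_index(drop=True)
    else:
        kind = ["snp" if p == 2 else "mtdna" for p in ploidy]
        loci = pd.DataFrame({"name": locus_cols, "kind": kind, "ploidy": ploidy})
    inds = df[meta].copy()
    if "year" in inds:
        inds["year"] = pd.to_numeric(inds["year"], errors="coerce")
    return GenotypeMatrix(inds, loci, alleles)


# ---------------------------------------------------------------------------
# Site tables and haplotypes
# ---------------------------------------------------------------------------

def read_sites(path) -> pd.DataFrame:
    """Read a site table CSV (code, lat, lon, year, stage[, distance_km])."""
    df = pd.read_csv(path)
    if df["code"].duplicated().any():
        raise ValueError("duplicate site codes")
    if not df["lat"].between(-90, 90).all():
        raise ValueError("latitude outside [-90, 90]")
    if not df["lon"].between(-180, 180).all():
        raise ValueError("longitude outside [-180, 180]")
    return df


def read_haplotypes(path) -> pd.DataFrame:
    """Read per-site haplotype counts (long CSV: site, haplotype, count).

    Returns a site x haplotype count table.
    """
    df = pd.read_csv(path)
    return df.pivot_table(index="site", columns="haplotype", values="count",
                          aggfunc="sum", fill_value=0)


def apply_quality_filter(matrix: GenotypeMatrix, max_failed_loci: int) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals with more than ``max_failed_loci`` missing loci.

    Returns the filtered matrix and the list of dropped individual IDs.
    """
    if max_failed_loci < 0:
        raise ValueError("max_failed_loci must be >= 0")
    failed = matrix.failed_loci_per_individual()
    keep = failed <= max_failed_loci
    dropped = list(matrix.individuals["id"][~keep])
    return matrix.subset_individuals(np.flatnonzero(keep)), dropped
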