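"""Genotype tables: data model, GENEPOP / delimited-table IO, duplicate matching.

Multilocus codominant genotypes (microsatellites) with per-individual
projected coordinates are the common currency of every analysis in this
package.  Alleles are positive integer codes (repeat sizes or arbitrary
labels); ``0`` is the missing sentinel in both slots of a genotype — a
half-missing call is coerced to fully missing on load.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeTable",
    "MatchReport",
    "read_genepop",
    "read_genotype_table",
    "write_genotype_table",
    "match_duplicates",
]


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with coordinates and metadata.

    Parameters
    ----------
    individual_id : array of str, shape (n,)
    alleles : int array, shape (n, L, 2)
        Positive allele codes; 0 = missing (always in both slots).
    locus_names : list of str, length L
    xy : float array, shape (n, 2)
        Projected planar coordinates in meters; NaN when unknown.
    sex : array of {'F', 'M', 'U'}, shape (n,)
    group : array of str, shape (n,), or None
        Optional per-individual label (genetic cluster or MU membership).
    """

    individual_id: np.ndarray
    alleles: np.ndarray
    locus_names: list[str]
    xy: np.ndarray | None = None
    sex: np.ndarray | None = None
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        n = len(self.individual_id)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, L, 2)")
        if self.alleles.shape[0] != n:
            raise ValueError("alleles and individual_id disagree on n")
        if n < 1:
            raise ValueError("need at least one individual")
        if len(self.locus_names) != self.alleles.shape[1]:
            raise ValueError("locus_names length must equal alleles.shape[1]")
        if np.any(self.alleles < 0):
            raise ValueError("allele codes must be positive or 0 (missing)")
        # coerce half-missing genotypes to fully missing
        half = (self.alleles == MISSING).any(axis=2)
        self.alleles[half] = MISSING
        if self.xy is None:
            self.xy = np.full((n, 2), np.nan)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (n, 2):
            raise ValueError("xy must have shape (n, 2)")
        if np.any(np.isinf(self.xy)):
            raise ValueError("coordinates must be finite or NaN")
        if self.sex is None:
            self.sex = np.full(n, "U", dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        if not set(np.unique(self.sex)) <= {"F", "M", "U"}:
            raise ValueError("sex codes must be F, M or U")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if self.group.shape[0] != n:
                raise ValueError("group length must equal n")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask of missing genotypes."""
        return (self.alleles == MISSING).all(axis=2)

    def subset(self, idx) -> "GenotypeTable":
        """Row subset (boolean mask or integer indices); copies."""
        idx = np.asarray(idx)
        return GenotypeTable(
            individual_id=self.individual_id[idx].copy(),
            alleles=self.alleles[idx].copy(),
            locus_names=list(self.locus_names),
            xy=self.xy[idx].copy(),
            sex=self.sex[idx].copy(),
            group=None if self.group is None else self.group[idx].copy(),
        )


@dataclass
class MatchReport:
    """Outcome of duplicate-genotype resolution."""

    n_input: int
    n_unique: int
    cluster_map: np.ndarray  # input index -> unique index
    mismatch_histogram: dict[int, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GENEPOP reader
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path) -> GenotypeTable:
    """Read a GENEPOP 4.x file (2- or 3-digit allele encoding).

    POP blocks become group labels (``POP1``, ``POP2``, ...); "00"/"000"
    decodes to missing.  Coordinates are absent (all NaN) — supply them via
    a companion delimited table if needed.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if len(lines) < 3:
        raise ValueError("not a GENEPOP file: too few lines")
    # title line, then locus names until first 'pop'
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no POP block found")
    ids, rows, groups = [], [], []
    pop_idx = 0
    digits = None  # 2 or 3, fixed for the whole file
    for lineno, ln in enumerate(lines[i:], start=i + 1):
        if _POP_RE.match(ln):
            pop_idx += 1
            continue
        if "," not in ln:
            raise ValueError(f"line {lineno}: expected 'id , genotypes'")
        ident, geno = ln.split(",", 1)
        fields = geno.split()
        if len(fields) != len(locus_names):
            raise ValueError(
                f"line {lineno}: {len(fields)} genotype fields for "
                f"{len(locus_names)} loci"
            )
        pair_row = []
        for tok in fields:
            if not tok.isdigit() or len(tok) not in (4, 6):
                raise ValueError(f"line {lineno}: malformed genotype field {tok!r}")
            w = len(tok) // 2
            if digits is None:
                digits = w
            elif w != digits:
                raise ValueError(
                    f"line {lineno}: mixed {2 * digits}- and {2 * w}-character "
                    "genotype fields"
                )
            pair_row.append((int(tok[:w]), int(tok[w:])))
        ids.append(ident.strip())
        rows.append(pair_row)
        groups.append(f"POP{pop_idx}")
    alleles = np.array(rows, dtype=np.int32)
    return GenotypeTable(
        individual_id=np.array(ids, dtype=object),
        alleles=alleles,
        locus_names=locus_names,
        group=np.array(groups, dtype=object),
    )


# ---------------------------------------------------------------------------
# Delimited genotype table
# ---------------------------------------------------------------------------


def read_genotype_table(path, sep: str = "\t") -> GenotypeTable:
    """Read the package's delimited genotype dialect.

    Columns: ``id``, ``sex``, ``x``, ``y``, optional ``group``, then two
    columns per locus named ``<locus>_1`` and ``<locus>_2``.  ``#`` starts a
    comment line.  Raw-sample ids must be unique (duplicate *genotypes* are
    resolved later by :func:`match_duplicates`, duplicate ids are an input
    error).
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"id": str})
    required = {"id", "sex", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"missing required columns: {sorted(required - set(df.columns))}")
    if df["id"].duplicated().any():
        dups = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"duplicated ids (must be raw-sample unique): {dups}")
    allele_cols = [c for c in df.columns if c.endswith("_1") or c.endswith("_2")]
    loci: list[str] = []
    for c in allele_cols:
        base = c[:-2]
        if base not in loci:
            loci.append(base)
    for base in loci:
        if f"{base}_1" not in df.columns or f"{base}_2" not in df.columns:
            raise ValueError(f"locus {base}: need both {base}_1 and {base}_2 columns")
    n = len(df)
    alleles = np.zeros((n, len(loci), 2), dtype=np.int32)
    for j, base in enumerate(loci):
        for k in (1, 2):
            col = df[f"{base}_{k}"]
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.isna() & col.notna()
            if bad.any():
                raise ValueError(
                    f"locus {base}: non-integer allele token "
                    f"{col[bad].iloc[0]!r}"
                )
            v = vals.fillna(MISSING)
            if not np.allclose(v, np.round(v)):
                raise ValueError(f"locus {base}: non-integer allele value")
            alleles[:, j, k - 1] = v.astype(np.int32)
    group = df["group"].astype(object).to_numpy() if "group" in df.columns else None
    return GenotypeTable(
        individual_id=df["id"].to_numpy(dtype=object),
        alleles=alleles,
        locus_names=loci,
        xy=df[["x", "y"]].to_numpy(dtype=float),
        sex=df["sex"].fillna("U").to_numpy(dtype=object),
        group=group,
    )


def write_genotype_table(table: GenotypeTable, path, sep: str = "\t") -> None:
    """Write the delimited dialect read by :func:`read_genotype_table`.

    Coordinates round to 6 decimals; the round-trip is bit-exact for integer
    alleles and 6-decimal coordinates.
    """
    data: dict[str, object] = {
        "id": table.individual_id,
        "sex": table.sex,
        "x": np.round(table.xy[:, 0], 6),
        "y": np.round(table.xy[:, 1], 6),
    }
    if table.group is not None:
        data["group"] = table.group
    for j, name in enumerate(table.locus_names):
        data[f"{name}_1"] = table.alleles[:, j, 0]
        data[f"{name}_2"] = table.alleles[:, j, 1]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Duplicate-genotype resolution
# ---------------------------------------------------------------------------


def _pairwise_match_counts(alleles: np.ndarray, ignore_missing: bool = False):
    """Counts of matching loci for every pair (unordered allele comparison).

    Returns (matches, comparable) where ``matches[i, j]`` is the number of
    loci at which both unordered genotypes are equal and complete, and
    ``comparable[i, j]`` the number complete in both.
    """
    srt = np.sort(alleles, axis=2)  # heterozygote AB == BA
    complete = ~(alleles == MISSING).all(axis=2)  # (n, L)
    eq = (srt[:, None, :, :] == srt[None, :, :, :]).all(axis=3)  # (n, n, L)
    both = complete[:, None, :] & complete[None, :, :]
    matches = (eq & both).sum(axis=2)
    comparable = both.sum(axis=2)
    return matches, comparable


def match_duplicates(
    table: GenotypeTable,
    min_matching_loci: int = 8,
    ignore_missing: bool = False,
) -> tuple[GenotypeTable, MatchReport]:
    """Collapse re-sampled individuals into unique genotypes.

    Two samples are linked when they agree at ``min_matching_loci`` or more
    loci (unordered allele pairs; a locus missing in either sample does not
    count as a match unless ``ignore_missing``, in which case the threshold
    is lowered by the number of jointly incomparable loci).  Connected
    components collapse to one individual: the representative is the member
    with fewest missing loci (ties broken by lowest input index), and its
    coordinates are the centroid of the member coordinates.
    """
    L = table.n_loci
    if min_matching_loci > L:
        raise ValueError(
            f"min_matching_loci={min_matching_loci} exceeds the number of loci ({L})"
        )
    matches, comparable = _pairwise_match_counts(table.alleles)
    if ignore_missing:
        thresh = np.maximum(min_matching_loci - (L - comparable), 1)
    else:
        thresh = min_matching_loci
    adj = matches >= thresh
    np.fill_diagonal(adj, False)
    n = table.n
    graph = coo_matrix(adj)
    n_comp, labels = connected_components(graph, directed=False)

    reps = np.empty(n_comp, dtype=int)
    n_missing = table.missing_mask().sum(axis=1)
    order = np.lexsort((np.arange(n), n_missing))  # fewest missing, then index
    seen = np.zeros(n_comp, dtype=bool)
    for i in order:
        c = labels[i]
        if not seen[c]:
            reps[c] = i
            seen[c] = True

    # relabel components so unique output preserves input order of reps
    rep_order = np.argsort(reps)
    old_to_new = np.empty(n_comp, dtype=int)
    old_to_new[rep_order] = np.arange(n_comp)
    labels = old_to_new[labels]
    reps = reps[rep_order]

    hist: Counter[int] = Counter()
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                i, j = members[a_i], members[b_i]
                mism = int(comparable[i, j] - matches[i, j]) + int(L - comparable[i, j])
                hist[mism] += 1

    out = table.subset(reps)
    for c in range(n_comp):
        members = labels == c
        if members.sum() > 1 and np.isfinite(table.xy[members]).any():
            with np.errstate(invalid="ignore"):
                out.xy[c] = np.nanmean(table.xy[members], axis=0)
    report = MatchReport(
        n_input=n,
        n_unique=n_comp,
        cluster_map=labels,
        mismatch_histogram=dict(sorted(hist.items())),
    )
    return out, report
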