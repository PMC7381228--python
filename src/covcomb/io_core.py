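"""Domain types and file I/O for labeled relationship data.

This module defines the carriers used throughout the package:

* :class:`LabeledMatrix` — a square symmetric matrix with ordered genotype
  (or trait) labels.  Every kernel in the package — a genomic relationship
  matrix ``G``, a pedigree additive relationship ``A``, a combined estimate
  ``Sigma`` — is a :class:`LabeledMatrix`.
* :class:`PartialSample` — a kernel observed on a subset of genotypes,
  optionally down-weighted; one Wishart observation for the combiner.
* :class:`Pedigree`, :class:`MarkerMatrix`, :class:`PhenotypeTable` — the
  raw-data containers that kernels are built from.

File dialect: plain CSV (UTF-8), a header row of labels and a first column
of labels for matrices; three columns (id, sire, dam) for pedigrees with
``0``/``NA``/empty denoting an unknown parent.  Matrices are symmetrized on
read as ``(M + M.T)/2``; a warning is emitted when the asymmetry exceeds
1e-6 because files assembled from heterogeneous sources drift.

Label matching is exact and case-sensitive everywhere: a silent merge of
``IR64`` and ``ir64`` is worse than a reported miss.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "NumericalError",
    "LabeledMatrix",
    "PartialSample",
    "Pedigree",
    "MarkerMatrix",
    "PhenotypeTable",
    "UNKNOWN_PARENT",
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_pedigree",
    "write_pedigree",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_phenotypes",
    "union_align",
]

UNKNOWN_PARENT = "0"
_UNKNOWN_CODES = {"0", "", "NA", "na", "nan", "NaN", "<NA>"}

#: relative asymmetry tolerated by the LabeledMatrix constructor
_SYM_RTOL = 1e-8
#: asymmetry on file triggering a warning on read
_READ_WARN_ASYM = 1e-6


class ValidationError(ValueError):
    """Raised when input data violates a structural precondition."""


class NumericalError(RuntimeError):
    """Raised when a linear-algebra step fails beyond repair (singularity)."""


def _check_unique(labels, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")
    return labels


@dataclass
class LabeledMatrix:
    """A square symmetric real matrix with ordered, unique labels.

    Parameters
    ----------
    labels
        Ordered unique identifier strings, one per row/column.
    values
        Square array of relationship/covariance values.  Must be symmetric
        to within a small relative tolerance; build from raw files via
        :func:`read_labeled_matrix`, which symmetrizes.
    source
        Optional free-text provenance ("GRM from panel d5", ...).
    n_features
        Number of markers/transcripts/records the matrix was computed from,
        when known.  Used by the combiner to pick a default Wishart degree
        of freedom.
    """

    labels: list[str]
    values: np.ndarray
    source: str | None = None
    n_features: int | None = None

    def __post_init__(self) -> None:
        self.labels = _check_unique(self.labels, "matrix labels")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {v.shape}")
        if v.shape[0] != len(self.labels):
            raise ValidationError(
                f"{len(self.labels)} labels for a {v.shape[0]}x{v.shape[1]} matrix"
            )
        scale = max(1.0, float(np.max(np.abs(v))) if v.size else 1.0)
        if v.size and float(np.max(np.abs(v - v.T))) > _SYM_RTOL * scale:
            raise ValidationError(
                "matrix is not symmetric; symmetrize first (read_labeled_matrix does)"
            )
        # store an exactly symmetric copy so downstream algebra never drifts
        self.values = (v + v.T) / 2.0
        if self.n_features is not None and self.n_features <= 0:
            raise ValidationError("n_features must be positive")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def submatrix(self, labels) -> "LabeledMatrix":
        """Restriction to ``labels`` (kept in the given order)."""
        idx = self.index
        missing = [l for l in labels if l not in idx]
        if missing:
            raise ValidationError(f"labels not in matrix: {missing}")
        sel = np.array([idx[l] for l in labels], dtype=int)
        return LabeledMatrix(
            list(labels), self.values[np.ix_(sel, sel)],
            source=self.source, n_features=self.n_features,
        )

    def reorder(self, labels) -> "LabeledMatrix":
        if sorted(labels) != sorted(self.labels):
            raise ValidationError("reorder requires the same label set")
        return self.submatrix(labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def copy(self) -> "LabeledMatrix":
        return LabeledMatrix(list(self.labels), self.values.copy(),
                             source=self.source, n_features=self.n_features)


@dataclass
class PartialSample:
    """A relationship matrix observed on a subset of genotypes.

    ``weight`` in [0, 1] down-weights the sample in the weighted EM: the
    observed block is replaced by ``w*G_a + (1-w)*nu*Psi_a`` at each
    iteration, so ``w=1`` is full trust in the data and ``w=0`` ignores it.
    """

    kernel: LabeledMatrix
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValidationError(f"weight must be in [0, 1], got {self.weight}")

    @property
    def labels(self) -> list[str]:
        return self.kernel.labels


@dataclass
class Pedigree:
    """Ordered parent records ``(id, sire, dam)`` with parents before offspring.

    Construction topologically sorts the records (deterministically: among
    ready individuals, lexicographic id order), appends implicit founder
    records for parents never listed as individuals, and rejects cycles.
    """

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        self.records = _toposort_pedigree(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def parents(self) -> dict[str, tuple[str, str]]:
        return {i: (s, d) for i, s, d in self.records}

    def __len__(self) -> int:
        return len(self.records)


def _norm_parent(p) -> str:
    p = "" if p is None else str(p).strip()
    return UNKNOWN_PARENT if p in _UNKNOWN_CODES else p


def _toposort_pedigree(records) -> list[tuple[str, str, str]]:
    recs = []
    for r in records:
        if len(r) != 3:
            raise ValidationError(f"pedigree record must have 3 fields: {r!r}")
        i, s, d = (str(r[0]).strip(), _norm_parent(r[1]), _norm_parent(r[2]))
        if i in _UNKNOWN_CODES:
            raise ValidationError(f"invalid individual id {r[0]!r}")
        recs.append((i, s, d))
    _check_unique([r[0] for r in recs], "pedigree ids")
    known = {r[0] for r in recs}
    parents_of = {i: (s, d) for i, s, d in recs}
    # implicit founders: parents never listed as individuals
    for i, s, d in list(recs):
        for p in (s, d):
            if p != UNKNOWN_PARENT and p not in known:
                recs.append((p, UNKNOWN_PARENT, UNKNOWN_PARENT))
                parents_of[p] = (UNKNOWN_PARENT, UNKNOWN_PARENT)
                known.add(p)
    # Kahn's algorithm, lexicographic among ready ids -> deterministic and
    # invariant to input row order
    children: dict[str, list[str]] = {i: [] for i in known}
    indeg = {}
    for i in known:
        s, d = parents_of[i]
        ps = [p for p in (s, d) if p != UNKNOWN_PARENT]
        if i in ps:
            raise ValidationError(f"cycle in pedigree: {i} is its own parent")
        indeg[i] = len(ps)
        for p in ps:
            children[p].append(i)
    ready = [i for i in known if indeg[i] == 0]
    heapq.heapify(ready)
    out = []
    while ready:
        i = heapq.heappop(ready)
        out.append((i, *parents_of[i]))
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(out) != len(known):
        cyc = sorted(i for i in known if indeg[i] > 0)
        raise ValidationError(f"cycle in pedigree involving: {cyc}")
    return out


@dataclass
class MarkerMatrix:
    """Genotype-by-marker dosage matrix; missing dosages stored as NaN.

    Dosages count copies of the reference allele, so lie in ``[0, ploidy]``;
    the default ploidy is 2 (diploid 0/1/2 coding).
    """

    genotype_labels: list[str]
    marker_labels: list[str]
    dosages: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.genotype_labels = _check_unique(self.genotype_labels, "genotype labels")
        self.marker_labels = _check_unique(self.marker_labels, "marker labels")
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.genotype_labels), len(self.marker_labels)):
            raise ValidationError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.genotype_labels)} genotypes x {len(self.marker_labels)} markers"
            )
        if self.ploidy <= 0 or self.ploidy % 2:
            raise ValidationError(f"ploidy must be a positive even integer, got {self.ploidy}")
        bad = np.argwhere(~np.isnan(d) & ((d < 0) | (d > self.ploidy)))
        if bad.size:
            g, m = bad[0]
            raise ValidationError(
                f"dosage {d[g, m]} outside [0, {self.ploidy}] at genotype "
                f"{self.genotype_labels[g]!r}, marker {self.marker_labels[m]!r}"
            )
        self.dosages = d

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_labels)

    @property
    def n_markers(self) -> int:
        return len(self.marker_labels)


@dataclass
class PhenotypeTable:
    """Long-format phenotype records (genotype, trait, value, dataset)."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("genotype", "trait", "value", "dataset")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        df = df[list(self.REQUIRED)].copy()
        for c in ("genotype", "trait", "dataset"):
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        keys = df[["genotype", "trait", "dataset"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicate (genotype, trait, dataset) key: {dup}")
        self.records = df.reset_index(drop=True)

    def trait_vector(self, trait: str) -> pd.Series:
        """Phenotypes for one trait, averaged over datasets per genotype."""
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise ValidationError(f"no records for trait {trait!r}")
        return sub.groupby("genotype")["value"].mean()

    def membership(self, trait: str) -> dict[str, str]:
        """genotype -> dataset map for one trait (first dataset wins)."""
        sub = self.records[self.records["trait"] == trait]
        return dict(zip(sub["genotype"], sub["dataset"]))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path, delimiter: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                           keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def read_labeled_matrix(path, delimiter: str = ",") -> LabeledMatrix:
    """Read a labeled square matrix from CSV, symmetrizing as ``(M+M')/2``.

    The file must carry a header row of labels and a first column of labels
    over the same set; the body must be fully numeric.
    """
    df = _read_table(path, delimiter)
    rows = _check_unique(df.index, "row labels")
    cols = _check_unique(df.columns, "column labels")
    if len(rows) != len(cols):
        raise ValidationError(
            f"{path}: body is {len(rows)}x{len(cols)}, not square"
        )
    if set(rows) != set(cols):
        raise ValidationError(f"{path}: row and column label sets differ")
    vals = np.empty((len(rows), len(cols)))
    for j, c in enumerate(df.columns):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.where(col.isna())[0]
        if bad.size:
            raise ValidationError(
                f"{path}: non-numeric cell at row {rows[bad[0]]!r}, column {c!r}"
            )
        vals[:, j] = col.to_numpy()
    # align columns to row order, then symmetrize
    order = [cols.index(r) for r in rows]
    vals = vals[:, order]
    asym = float(np.max(np.abs(vals - vals.T))) if vals.size else 0.0
    if asym > _READ_WARN_ASYM * max(1.0, float(np.max(np.abs(vals)))):
        warnings.warn(f"{path}: asymmetry {asym:.3g} averaged out on read")
    return LabeledMatrix(rows, (vals + vals.T) / 2.0, source=str(path))


def write_labeled_matrix(m: LabeledMatrix, path, delimiter: str = ",") -> None:
    df = m.to_dataframe()
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_pedigree(path, delimiter: str = ",") -> Pedigree:
    """Read a 3-column (id, sire, dam) pedigree; ``0``/``NA``/empty = unknown.

    A header row is tolerated (detected by non-id duplication heuristics is
    fragile, so: a first row whose id is one of ``id``/``ID``/``Id`` is
    treated as a header).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, header=None,
                     keep_default_na=False)
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: pedigree needs 3 columns, got {df.shape[1]}")
    rows = df.iloc[:, :3].values.tolist()
    if rows and str(rows[0][0]).strip().lower() in {"id", "genotype", "individual"}:
        rows = rows[1:]
    return Pedigree([(r[0], r[1], r[2]) for r in rows])


def write_pedigree(ped: Pedigree, path, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, s, d in ped.records:
            fh.write(delimiter.join((i, s, d)) + "\n")


def read_marker_matrix(path, ploidy: int = 2, delimiter: str = ",") -> MarkerMatrix:
    """Read a genotype-by-marker dosage CSV (header = markers, col 0 = genotypes).

    ``NA``/empty cells become missing; dosage bounds are checked against
    ``ploidy`` (tetraploid 0..4 coding is accepted with ``ploidy=4``).
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    genos = _check_unique(df.index, "genotype labels")
    markers = _check_unique(df.columns, "marker labels")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw = df.astype(str).to_numpy()
    bad = np.argwhere(np.isnan(vals)
                      & ~np.isin(np.char.strip(raw.astype(str)),
                                 ("", "NA", "na", "nan", "NaN", "<NA>", "None")))
    if bad.size:
        g, m = bad[0]
        raise ValidationError(
            f"{path}: non-numeric dosage at genotype {genos[g]!r}, marker {markers[m]!r}"
        )
    return MarkerMatrix(genos, markers, vals, ploidy=ploidy)


def write_marker_matrix(m: MarkerMatrix, path, delimiter: str = ",") -> None:
    pd.DataFrame(m.dosages, index=m.genotype_labels,
                 columns=m.marker_labels).to_csv(path, sep=delimiter)


def read_phenotypes(path, delimiter: str = ",") -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep=delimiter))


def write_phenotypes(p: PhenotypeTable, path, delimiter: str = ",") -> None:
    p.records.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# label alignment
# ---------------------------------------------------------------------------

def union_align(samples: list[PartialSample]) -> tuple[list[str], list[np.ndarray]]:
    """Sorted union of sample label sets plus per-sample index maps.

    Returns ``(K, maps)`` where ``K`` is the sorted union of all sample
    labels and ``maps[i][j]`` is the position in ``K`` of sample *i*'s
    *j*-th label.  The maps play the role of the permutation matrices that
    align each partial matrix with the union — realized as integer index
    vectors, which is mathematically identical and avoids O(n^2) products.

    The output is invariant to the order in which samples are supplied.
    """
    if not samples:
        raise ValidationError("union_align requires at least one sample")
    union: set[str] = set()
    for s in samples:
        union.update(s.labels)
    K = sorted(union)
    pos = {lab: i for i, lab in enumerate(K)}
    maps = [np.array([pos[l] for l in s.labels], dtype=int) for s in samples]
    return K, maps
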