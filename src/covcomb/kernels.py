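"""Relationship-kernel constructors and covariance utilities.

Two standard kernels over genotypes:

* :func:`grm_vanraden` — the marker-based genomic relationship matrix
  ``G = ZZ' / (2 * sum_j p_j (1 - p_j))`` with ``Z = M - 2p`` (VanRaden
  method 1, observed allele frequencies).
* :func:`amatrix_tabular` — the pedigree-based additive (numerator)
  relationship matrix by the tabular/recursive method.

plus :func:`cov2cor` (covariance -> correlation) and :func:`ensure_psd`
(spectral clip repair), used when combining correlation matrices from
phenotypic trials or when an input kernel is indefinite.
"""

from __future__ import annotations

import numpy as np

from .io_core import LabeledMatrix, MarkerMatrix, Pedigree, ValidationError

__all__ = ["grm_vanraden", "amatrix_tabular", "cov2cor", "ensure_psd"]


def grm_vanraden(m: MarkerMatrix) -> LabeledMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Allele frequencies are estimated per marker from the non-missing
    dosages of the panel itself; missing dosages are mean-imputed before
    centering; monomorphic (zero-variance) markers are dropped.  The
    resulting ``G`` is positive semi-definite by construction and its
    ``n_features`` records the number of markers actually used.

    Raises
    ------
    ValidationError
        If fewer than two genotypes are supplied, the ploidy is not 2, or
        no informative (polymorphic) marker remains.
    """
    if m.n_genotypes < 2:
        raise ValidationError("GRM needs at least 2 genotypes")
    if m.ploidy != 2:
        raise ValidationError(
            f"grm_vanraden implements the diploid formula; got ploidy {m.ploidy}"
        )
    D = m.dosages
    with np.errstate(invalid="ignore"):
        p = np.nanmean(D, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValidationError("no informative markers (all monomorphic or missing)")
    D = D[:, keep]
    p = p[keep]
    # per-marker mean imputation == set missing residual to zero after centering
    Z = D - 2.0 * p
    Z[np.isnan(Z)] = 0.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    return LabeledMatrix(
        list(m.genotype_labels), (G + G.T) / 2.0,
        source="grm_vanraden", n_features=int(keep.sum()),
    )


def amatrix_tabular(ped: Pedigree) -> LabeledMatrix:
    """Additive relationship matrix by the tabular (recursive) method.

    With individuals sorted parents-first, for each ``i`` with parents
    ``s, d`` (unknown parents contributing zero):

    ``a(i, j) = 0.5 * (a(j, s) + a(j, d))`` for every earlier ``j``, and
    ``a(i, i) = 1 + 0.5 * a(s, d)``.

    Founders are unrelated and non-inbred (diagonal 1).  Diploid only.
    """
    ids = ped.ids
    pos = {g: k for k, g in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for k, (i, s, d) in enumerate(ped.records):
        si = pos.get(s, -1) if s != "0" else -1
        di = pos.get(d, -1) if d != "0" else -1
        row = np.zeros(k)
        if si >= 0:
            row += 0.5 * A[si, :k]
        if di >= 0:
            row += 0.5 * A[di, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return LabeledMatrix(ids, A, source="amatrix_tabular")


def cov2cor(k: LabeledMatrix) -> LabeledMatrix:
    """Convert a covariance matrix to the correlation matrix.

    ``r_ij = k_ij / sqrt(k_ii * k_jj)``; idempotent on correlation
    matrices.  Raises on a zero or negative diagonal entry, naming the
    offending label.
    """
    d = np.diag(k.values)
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"non-positive diagonal for label {k.labels[bad[0]]!r}: {d[bad[0]]}"
        )
    s = 1.0 / np.sqrt(d)
    R = k.values * np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return LabeledMatrix(list(k.labels), (R + R.T) / 2.0,
                         source=k.source, n_features=k.n_features)


def ensure_psd(k: LabeledMatrix, jitter: float = 0.0) -> LabeledMatrix:
    """Repair an indefinite symmetric matrix by clipping eigenvalues at zero.

    The clip is the Frobenius-nearest PSD matrix; ``jitter`` is then added
    to the diagonal so the minimum eigenvalue is at least ``jitter``.
    """
    if jitter < 0:
        raise ValidationError("jitter must be non-negative")
    w, U = np.linalg.eigh(k.values)
    if w[0] >= 0 and jitter == 0.0:
        return k.copy()
    w = np.clip(w, 0.0, None)
    V = (U * w) @ U.T
    V = (V + V.T) / 2.0
    if jitter:
        V[np.diag_indices_from(V)] += jitter
    return LabeledMatrix(list(k.labels), V, source=k.source, n_features=k.n_features)
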