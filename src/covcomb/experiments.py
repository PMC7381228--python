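"""Desk-scale replications of the validation designs, plus the imputation baseline.

Two experiment harnesses reproduce, on synthetic data, the qualitative
shapes the combiner is expected to show:

* :func:`run_anchor_experiment` — two disconnected pedigree relationship
  matrices anchored by a genomic relationship matrix built on a genotyped
  subsample drawn half-and-half from each pedigree.  The combined estimate
  of the cross-pedigree (never observed) relationships is scored against
  the full-pedigree A-matrix; accuracy should rise with the number of
  genotyped anchors.
* :func:`run_combine_vs_impute` — many small random genotype x marker
  panels drawn from one ground-truth panel.  Route (i) builds a GRM per
  panel and combines them with the Wishart EM; route (ii) assembles the
  union genotype x marker matrix (un-genotyped cells missing), completes
  it by low-rank soft-impute, and builds a single GRM from the completed
  matrix.  Both are scored against the ground-truth GRM, overall and on
  entries observed in no panel.

The imputation baseline is the soft-threshold SVD low-rank completion
(:func:`soft_impute`), the matrix-factorization method used as the
feature-imputation comparator.

The defaults are deliberately desk-scale (hundreds of genotypes, thousands
of markers): the acceptance surface is the *trend* — accuracy versus the
number of panels, combining versus imputing — not the magnitudes reported
for the full-size datasets, which require external downloads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds

from .combine import EMConfig, combine_em
from .io_core import LabeledMatrix, MarkerMatrix, PartialSample, ValidationError
from .kernels import amatrix_tabular, grm_vanraden
from .synthetic import simulate_pedigree_genedrop, simulate_structured_markers

__all__ = [
    "AccuracyReport",
    "soft_impute",
    "evaluate_estimate",
    "run_anchor_experiment",
    "run_combine_vs_impute",
]


@dataclass
class AccuracyReport:
    """Replicate-by-condition accuracy rows with run parameters attached."""

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            if (t["mse"] < 0).any():
                raise ValidationError("negative MSE in report")
            if ((t["correlation"] < -1 - 1e-12) | (t["correlation"] > 1 + 1e-12)).any():
                raise ValidationError("correlation outside [-1, 1]")
            if (t["n_entries"] <= 0).any():
                raise ValidationError("n_entries must be positive")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        group_cols = [c for c in self.table.columns
                      if c not in ("replicate", "mse", "correlation", "n_entries")]
        g = self.table.groupby(group_cols)[["mse", "correlation"]].mean()
        return g.to_string()


# ---------------------------------------------------------------------------
# low-rank completion baseline
# ---------------------------------------------------------------------------

def _truncated_svd(Z: np.ndarray, rank: int):
    # dense LAPACK SVD beats ARPACK for the short-and-wide matrices this
    # package sees (hundreds of genotypes); fall back to svds when tall
    if min(Z.shape) <= 600 or rank >= min(Z.shape) - 1:
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        return U[:, :rank], s[:rank], Vt[:rank]
    U, s, Vt = svds(Z, k=min(rank, min(Z.shape) - 1))
    order = np.argsort(s)[::-1]
    return U[:, order], s[order], Vt[order]


def soft_impute(
    m: MarkerMatrix,
    rank: int | None = None,
    lam: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> MarkerMatrix:
    """Low-rank completion of a dosage matrix by soft-thresholded SVD.

    Missing entries are initialized at the column means and the matrix is
    repeatedly replaced by its rank-``rank`` SVD reconstruction with
    singular values shrunk by ``lam``, observed entries being restored
    after every pass.  Iteration stops when the relative change of the
    imputed matrix drops below ``tol``.  Observed entries of the output
    equal the input exactly; imputed entries are clipped to
    ``[0, ploidy]``.
    """
    X = m.dosages
    obs = ~np.isnan(X)
    if (obs.sum(axis=1) == 0).any():
        g = int(np.where(obs.sum(axis=1) == 0)[0][0])
        raise ValidationError(f"genotype {m.genotype_labels[g]!r} has no observed dosage")
    if (obs.sum(axis=0) == 0).any():
        j = int(np.where(obs.sum(axis=0) == 0)[0][0])
        raise ValidationError(f"marker {m.marker_labels[j]!r} has no observed dosage")
    if lam < 0:
        raise ValidationError("lam must be non-negative")
    rank = min(50, min(X.shape)) if rank is None else int(rank)

    if obs.all():
        return MarkerMatrix(list(m.genotype_labels), list(m.marker_labels),
                            X.copy(), ploidy=m.ploidy)

    col_means = np.nanmean(X, axis=0)
    Z = np.where(obs, X, col_means)
    for _ in range(max_iter):
        U, s, Vt = _truncated_svd(Z, rank)
        s = np.clip(s - lam, 0.0, None)
        Znew = (U * s) @ Vt
        Znew[obs] = X[obs]
        denom = max(np.linalg.norm(Z), 1e-30)
        delta = np.linalg.norm(Znew - Z) / denom
        Z = Znew
        if delta < tol:
            break
    out = np.clip(Z, 0.0, m.ploidy)
    out[obs] = X[obs]
    return MarkerMatrix(list(m.genotype_labels), list(m.marker_labels), out,
                        ploidy=m.ploidy)


def evaluate_estimate(
    estimate: LabeledMatrix,
    truth: LabeledMatrix,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """MSE and Pearson correlation over selected upper-triangle entries.

    ``mask`` (symmetric boolean, aligned to the label order) selects the
    entries to score; ``None`` scores everything.  The diagonal is
    included.  Labels of estimate and truth must agree as sets; the truth
    is reordered to the estimate.
    """
    if set(estimate.labels) != set(truth.labels):
        raise ValidationError("estimate and truth must carry the same labels")
    T = truth.reorder(estimate.labels).values
    E = estimate.values
    n = estimate.n
    iu = np.triu_indices(n)
    sel = np.ones(len(iu[0]), dtype=bool) if mask is None else np.asarray(mask)[iu]
    if sel.sum() == 0:
        raise ValidationError("mask selects no entries")
    e = E[iu][sel]
    t = T[iu][sel]
    mse = float(np.mean((e - t) ** 2))
    if len(e) < 2 or np.std(e) == 0 or np.std(t) == 0:
        corr = np.nan
    else:
        corr = float(np.corrcoef(e, t)[0, 1])
    return mse, corr


# ---------------------------------------------------------------------------
# experiment harnesses
# ---------------------------------------------------------------------------

def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_anchor_experiment(
    n_per_pedigree: int,
    n_genotyped_per_pedigree: int | list[int],
    n_markers: int = 2000,
    reps: int = 20,
    seed: int = 0,
    em_tol: float = 1e-6,
    em_max_iter: int = 200,
) -> AccuracyReport:
    """Anchor two disconnected pedigree kernels with a genomic kernel.

    Per replicate: a random-mating pedigree is simulated with gene-drop
    genotypes; ``2 * n_per_pedigree`` recent individuals are split at
    random into two groups whose pedigree A-matrices are taken as two
    disconnected partial samples; ``n_genotyped_per_pedigree`` individuals
    from each group are "genotyped" and their marker GRM forms the third,
    bridging sample.  The combined estimate is scored against the
    full-pedigree A on the entries observed in no sample (the
    cross-pedigree block minus the genotyped corner).
    """
    sizes = ([n_genotyped_per_pedigree]
             if np.isscalar(n_genotyped_per_pedigree) else list(n_genotyped_per_pedigree))
    for g in sizes:
        if g < 2 or g > n_per_pedigree:
            raise ValidationError(
                f"n_genotyped_per_pedigree={g} not in [2, {n_per_pedigree}]"
            )
    if n_per_pedigree < 4:
        raise ValidationError("n_per_pedigree must be >= 4")
    rows = []
    seeds = _child_seeds(seed, reps)
    for rep, rs in enumerate(seeds):
        rng = np.random.default_rng(rs)
        nf = n_per_pedigree + (n_per_pedigree % 2)
        ped, markers = simulate_pedigree_genedrop(
            n_founders=nf, n_generations=3, offspring_per_cross=2,
            n_markers=n_markers, seed=rs,
        )
        A_full = amatrix_tabular(ped)
        # pool: the two most recent generations (descendants, inter-related)
        pool = ped.ids[-2 * nf:]
        chosen = list(rng.choice(pool, size=2 * n_per_pedigree, replace=False))
        grp1 = sorted(chosen[:n_per_pedigree])
        grp2 = sorted(chosen[n_per_pedigree:])
        K = sorted(grp1 + grp2)
        truth = A_full.submatrix(K)
        gpos = {g: i for i, g in enumerate(markers.genotype_labels)}
        for g in sizes:
            anchors = (list(rng.choice(grp1, size=g, replace=False))
                       + list(rng.choice(grp2, size=g, replace=False)))
            rowsel = [gpos[a] for a in anchors]
            G = grm_vanraden(MarkerMatrix(anchors, markers.marker_labels,
                                          markers.dosages[rowsel]))
            samples = [
                PartialSample(A_full.submatrix(grp1)),
                PartialSample(A_full.submatrix(grp2)),
                PartialSample(G),
            ]
            res = combine_em(samples, EMConfig(tol=em_tol, max_iter=em_max_iter))
            est = res.sigma.reorder(truth.labels)
            idx = {l: i for i, l in enumerate(res.sigma.labels)}
            perm = [idx[l] for l in truth.labels]
            mask = res.observed_mask[np.ix_(perm, perm)]
            mse, corr = evaluate_estimate(est, truth, mask=~mask)
            rows.append({
                "replicate": rep, "n_per_pedigree": n_per_pedigree,
                "n_genotyped": g, "mse": mse, "correlation": corr,
                "n_entries": int(np.triu(~mask).sum()),
            })
    return AccuracyReport(pd.DataFrame(rows), params={
        "n_per_pedigree": n_per_pedigree, "sizes": sizes,
        "n_markers": n_markers, "reps": reps, "seed": seed,
    })


def _select_soft_impute_lambda(X, obs, rank, grid=(0.0, 5.0, 20.0), holdout=0.05,
                               seed=0):
    """Pick lambda by masking a holdout of observed entries and refitting."""
    rng = np.random.default_rng(seed)
    oi = np.argwhere(obs)
    k = max(1, int(holdout * len(oi)))
    hold = oi[rng.choice(len(oi), size=k, replace=False)]
    Xh = X.copy()
    Xh[hold[:, 0], hold[:, 1]] = np.nan
    mm = MarkerMatrix([f"r{i}" for i in range(X.shape[0])],
                      [f"c{j}" for j in range(X.shape[1])], Xh)
    best, best_err = grid[0], np.inf
    for lam in grid:
        try:
            filled = soft_impute(mm, rank=rank, lam=lam, max_iter=30, tol=1e-4)
        except ValidationError:
            continue
        err = float(np.mean(
            (filled.dosages[hold[:, 0], hold[:, 1]] - X[hold[:, 0], hold[:, 1]]) ** 2
        ))
        if err < best_err:
            best, best_err = lam, err
    return best


def run_combine_vs_impute(
    n_total: int = 300,
    n_kernels: int = 10,
    genotypes_per_kernel: int = 100,
    markers_per_kernel: int = 500,
    reps: int = 20,
    seed: int = 0,
    n_markers_truth: int = 5000,
    em_tol: float = 1e-5,
    em_max_iter: int = 150,
    impute_rank: int | None = None,
    n_subpops: int = 3,
    fst: float = 0.2,
    family_size: int = 5,
) -> AccuracyReport:
    """Compare relationship combining against marker imputation.

    Per replicate a ground-truth panel of ``n_total`` genotypes and
    ``n_markers_truth`` markers, drawn from a structured population
    (``n_subpops`` subpopulations at differentiation ``fst``, the regime
    of real diversity panels), defines the true GRM.  ``n_kernels``
    sub-panels of ``genotypes_per_kernel x markers_per_kernel`` are drawn
    by randomly sampling genotypes and markers; the two routes described
    in the module docstring are run and scored against the truth on the
    genotypes covered by at least one panel, both over all entries and
    over the entries observed in no panel.  Report rows carry
    ``method`` in {"combined", "imputed"} and ``scope`` in
    {"all", "unobserved"}.
    """
    if genotypes_per_kernel > n_total or markers_per_kernel > n_markers_truth:
        raise ValidationError("sub-panel larger than the ground-truth panel")
    rows = []
    seeds = _child_seeds(seed, reps)
    lam_chosen: float | None = None
    for rep, rs in enumerate(seeds):
        rng = np.random.default_rng(rs)
        panel = simulate_structured_markers(n_total, n_markers_truth,
                                            n_subpops=n_subpops, fst=fst,
                                            family_size=family_size, seed=rs)
        truth = grm_vanraden(panel)
        gl = np.array(panel.genotype_labels)
        samples = []
        marker_sets = []
        geno_sets = []
        for _ in range(n_kernels):
            gi = np.sort(rng.choice(n_total, size=genotypes_per_kernel, replace=False))
            mi = np.sort(rng.choice(n_markers_truth, size=markers_per_kernel,
                                    replace=False))
            sub = MarkerMatrix([gl[i] for i in gi],
                               [panel.marker_labels[j] for j in mi],
                               panel.dosages[np.ix_(gi, mi)])
            samples.append(PartialSample(grm_vanraden(sub)))
            marker_sets.append(mi)
            geno_sets.append(gi)

        res = combine_em(samples, EMConfig(tol=em_tol, max_iter=em_max_iter))
        K = res.sigma.labels
        truth_K = truth.submatrix(K)
        mask = res.observed_mask

        # imputation route: union genotype x marker matrix with missing cells
        union_m = np.sort(np.unique(np.concatenate(marker_sets)))
        gpos = {g: i for i, g in enumerate(K)}
        mpos = {j: i for i, j in enumerate(union_m)}
        Xu = np.full((len(K), len(union_m)), np.nan)
        for gi, mi in zip(geno_sets, marker_sets):
            rsel = np.array([gpos[gl[i]] for i in gi])
            csel = np.array([mpos[j] for j in mi])
            Xu[np.ix_(rsel, csel)] = panel.dosages[np.ix_(gi, mi)]
        rank = impute_rank if impute_rank is not None else min(50, *Xu.shape)
        if lam_chosen is None:
            lam_chosen = _select_soft_impute_lambda(Xu, ~np.isnan(Xu), rank, seed=rs)
        filled = soft_impute(
            MarkerMatrix(K, [panel.marker_labels[j] for j in union_m], Xu),
            rank=rank, lam=lam_chosen, max_iter=30, tol=1e-4,
        )
        G_imp = grm_vanraden(filled)

        for method, est in (("combined", res.sigma), ("imputed", G_imp)):
            for scope, msk in (("all", None), ("unobserved", ~mask)):
                if msk is not None and not np.triu(msk).any():
                    continue
                mse, corr = evaluate_estimate(est, truth_K, mask=msk)
                n_e = (len(K) * (len(K) + 1) // 2 if msk is None
                       else int(np.triu(msk).sum()))
                rows.append({
                    "replicate": rep, "n_kernels": n_kernels, "method": method,
                    "scope": scope, "mse": mse, "correlation": corr,
                    "n_entries": n_e,
                })
    return AccuracyReport(pd.DataFrame(rows), params={
        "n_total": n_total, "n_kernels": n_kernels,
        "genotypes_per_kernel": genotypes_per_kernel,
        "markers_per_kernel": markers_per_kernel, "reps": reps, "seed": seed,
        "n_markers_truth": n_markers_truth, "soft_impute_lambda": lam_chosen,
        "soft_impute_rank": impute_rank if impute_rank is not None else "min(50,dims)",
    })
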