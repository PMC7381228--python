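"""Mixed-model genomic prediction: G-BLUP, multi-kernel BLUP, cross-validation.

The model is the standard animal/plant-breeding mixed model with an
intercept-only fixed effect,

    ``y = 1*mu + g + e``,  ``g ~ N(0, sigma_g^2 K)``,  ``e ~ N(0, sigma_e^2 I)``,

fitted by REML.  For a single kernel the REML profile over the variance
ratio ``lambda = sigma_g^2 / sigma_e^2`` is maximized on the spectrum of
the kernel restricted to the intercept's orthogonal complement (one
eigendecomposition, then 1-D optimization).  For several kernels
(e.g. a genomic and a transcriptomic relationship matrix)

    ``y = 1*mu + sum_k g_k + e``,  ``g_k ~ N(0, sigma_k^2 K_k)``

is fitted by EM-REML iterations followed by a quasi-Newton polish of the
REML log-likelihood in log-variance coordinates (EM alone converges too
slowly near the optimum to hand variance components over at tight
tolerance).

Genomic estimated breeding values (GEBVs) for unphenotyped genotypes are
conditional means through the kernel: ``g_test = K_21 K_11^{-1} g_train``.
Prediction accuracy is the Pearson correlation between GEBVs and observed
phenotypes, computed per cross-validation fold (random folds) or per held
dataset (leave-one-dataset-out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .io_core import LabeledMatrix, NumericalError, ValidationError

__all__ = [
    "MixedModelFit",
    "GBLUP",
    "MultiKernelGBLUP",
    "CVResult",
    "reml_spectral",
    "multikernel_reml",
    "gblup_predict",
    "cv_random_folds",
    "cv_leave_dataset_out",
]

_RATIO_BOUNDS = (-12.0, 12.0)  # log10(lambda) search window


@dataclass
class MixedModelFit:
    """REML fit of a (multi-)kernel mixed model.

    ``var_components`` holds one genetic variance per kernel followed by
    the residual variance.  ``genotype_effects`` are the BLUPs (GEBVs) of
    the training genotypes (summed over kernels for multi-kernel fits);
    ``h2`` is the ratio of total genetic to total phenotypic variance.
    """

    var_components: np.ndarray
    fixed_effects: np.ndarray
    genotype_effects: pd.Series
    h2: float
    loglik: float = np.nan
    converged: bool = True
    method: str = "reml_spectral"
    per_kernel_effects: list[pd.Series] | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.var_components) < 0):
            raise ValidationError("variance components must be non-negative")

    @property
    def train_labels(self) -> list[str]:
        return list(self.genotype_effects.index)

    def summary(self) -> str:
        vc = self.var_components
        names = [f"sigma2_k{i + 1}" for i in range(len(vc) - 1)] + ["sigma2_e"]
        lines = [
            f"Mixed-model REML fit ({self.method})",
            "=" * 40,
            f"n (training genotypes) : {len(self.genotype_effects)}",
            *(f"{nm:<22} : {v:.6g}" for nm, v in zip(names, vc)),
            f"{'h2':<22} : {self.h2:.4f}",
            f"{'intercept':<22} : {self.fixed_effects[0]:.6g}",
            f"{'REML log-likelihood':<22} : {self.loglik:.4f}",
        ]
        if not self.converged:
            lines.append("WARNING: iteration limit reached")
        return "\n".join(lines)


def _align(y: pd.Series, k: LabeledMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = pd.Series(y).dropna()
    labels = [str(l) for l in y.index]
    missing = [l for l in labels if l not in k.index]
    if missing:
        raise ValidationError(f"phenotyped genotypes missing from kernel: {missing[:5]}")
    K = k.submatrix(labels).values
    return y.to_numpy(dtype=float), K, labels


def reml_spectral(y: pd.Series, k: LabeledMatrix) -> MixedModelFit:
    """Single-kernel REML via the spectral profile of the variance ratio.

    Eigen-decomposes the kernel on the orthogonal complement of the
    intercept, then maximizes the REML log-likelihood over
    ``lambda = sigma_g^2/sigma_e^2`` by bounded 1-D search; the residual
    variance is profiled out analytically.  GEBVs are the BLUPs
    ``lambda K (lambda K + I)^{-1} (y - mu)``.
    """
    yv, K, labels = _align(y, k)
    n = len(yv)
    if n < 3:
        raise ValidationError(f"need at least 3 phenotyped genotypes, got {n}")

    if float(np.var(yv)) < 1e-14:
        # degenerate: no phenotypic variance at all
        return MixedModelFit(
            var_components=np.array([0.0, 0.0]),
            fixed_effects=np.array([float(np.mean(yv))]),
            genotype_effects=pd.Series(np.zeros(n), index=labels),
            h2=0.0, loglik=np.nan, method="reml_spectral",
        )

    # contrast basis orthogonal to the intercept
    X = np.ones((n, 1))
    Q, _ = np.linalg.qr(X, mode="complete")
    Acon = Q[:, 1:]                                   # n x (n-1)
    M = Acon.T @ K @ Acon
    xi, V = np.linalg.eigh((M + M.T) / 2.0)
    xi = np.clip(xi, 0.0, None)
    if xi[-1] - xi[0] < 1e-12 * max(1.0, xi[-1]):
        raise ValidationError(
            "kernel is proportional to the identity on the contrast space; "
            "genetic and residual variance are not separately identifiable"
        )
    eta = (Acon @ V).T @ yv                           # rotated contrasts

    def neg_restricted_ll(log10_lam: float) -> float:
        lam = 10.0 ** log10_lam
        d = lam * xi + 1.0
        s2 = float(np.sum(eta ** 2 / d)) / (n - 1)
        return 0.5 * (float(np.sum(np.log(d))) + (n - 1) * np.log(s2))

    grid = np.linspace(*_RATIO_BOUNDS, 49)
    vals = [neg_restricted_ll(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(10.0 ** res.x)
    # boundary: essentially no genetic signal
    if res.x <= _RATIO_BOUNDS[0] + 1e-6:
        lam = 0.0
    d = lam * xi + 1.0
    s2e = float(np.sum(eta ** 2 / d)) / (n - 1)
    s2g = lam * s2e
    ll = -neg_restricted_ll(np.log10(lam) if lam > 0 else _RATIO_BOUNDS[0]) \
        - 0.5 * (n - 1) * (1.0 + np.log(2.0 * np.pi))

    mu, ghat = _blup_given_ratio(yv, K, lam)
    return MixedModelFit(
        var_components=np.array([s2g, s2e]),
        fixed_effects=np.array([mu]),
        genotype_effects=pd.Series(ghat, index=labels),
        h2=s2g / (s2g + s2e) if (s2g + s2e) > 0 else 0.0,
        loglik=float(ll), method="reml_spectral",
    )


def _blup_given_ratio(yv: np.ndarray, K: np.ndarray, lam: float):
    """GLS intercept and BLUPs at a fixed variance ratio lambda."""
    n = len(yv)
    V0 = lam * K + np.eye(n)
    c = cho_factor((V0 + V0.T) / 2.0, lower=True, check_finite=False)
    Vi1 = cho_solve(c, np.ones(n), check_finite=False)
    mu = float(Vi1 @ yv) / float(Vi1.sum())
    r = yv - mu
    ghat = lam * (K @ cho_solve(c, r, check_finite=False))
    return mu, ghat


class GBLUP:
    """Single-kernel G-BLUP model: ``GBLUP(y, kernel).fit()``.

    ``y`` is a pandas Series indexed by genotype labels contained in the
    kernel.  ``fit()`` returns a :class:`MixedModelFit`; predictions for
    genotypes without phenotypes come from
    :meth:`predict`/:func:`gblup_predict`.
    """

    def __init__(self, y: pd.Series, kernel: LabeledMatrix):
        self.y = pd.Series(y)
        self.kernel = kernel

    def fit(self) -> MixedModelFit:
        fit = reml_spectral(self.y, self.kernel)
        fit._model = self  # noqa: SLF001 - convenience backref
        return fit

    def predict(self, fit: MixedModelFit, test_labels) -> pd.Series:
        return gblup_predict(fit, self.kernel, test_labels)


def gblup_predict(fit: MixedModelFit, k_full: LabeledMatrix, test_labels) -> pd.Series:
    """GEBVs for unphenotyped genotypes via the kernel conditional mean.

    ``g_test = K_21 K_11^{-1} g_train`` where 1 indexes the training
    genotypes of ``fit`` and 2 the requested ``test_labels``.  A test
    genotype unrelated to all training genotypes gets the prior mean 0; a
    test genotype whose kernel row equals a training genotype's row gets
    that genotype's GEBV.
    """
    test_labels = [str(l) for l in test_labels]
    missing = [l for l in test_labels if l not in k_full.index]
    if missing:
        raise ValidationError(f"test genotypes absent from kernel: {missing[:5]}")
    train = fit.train_labels
    missing = [l for l in train if l not in k_full.index]
    if missing:
        raise ValidationError(f"training genotypes absent from kernel: {missing[:5]}")
    idx = k_full.index
    i1 = np.array([idx[l] for l in train], dtype=int)
    i2 = np.array([idx[l] for l in test_labels], dtype=int)
    K11 = k_full.values[np.ix_(i1, i1)]
    K21 = k_full.values[np.ix_(i2, i1)]
    ghat = fit.genotype_effects.to_numpy(dtype=float)
    scale = max(float(np.mean(np.diag(K11))), np.finfo(float).tiny)
    for eps in (1e-10, 1e-8, 1e-6):
        try:
            c = cho_factor(K11 + eps * scale * np.eye(len(i1)), lower=True,
                           check_finite=False)
            break
        except LinAlgError:
            continue
    else:
        raise NumericalError("training kernel block is numerically singular")
    pred = K21 @ cho_solve(c, ghat, check_finite=False)
    return pd.Series(pred, index=test_labels, name="gebv")


# ---------------------------------------------------------------------------
# multi-kernel REML
# ---------------------------------------------------------------------------

def _reml_pieces(yv, X, Ks, s2):
    """V, P y, restricted log-likelihood and per-component gradients."""
    n = len(yv)
    V = s2[-1] * np.eye(n)
    for sk, K in zip(s2[:-1], Ks):
        V += sk * K
    c = cho_factor((V + V.T) / 2.0, lower=True, check_finite=False)
    ViX = cho_solve(c, X, check_finite=False)
    XtViX = X.T @ ViX
    Viy = cho_solve(c, yv, check_finite=False)
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    Py = Viy - ViX @ np.linalg.solve(XtViX, ViX.T @ yv)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    ll = -0.5 * (logdetV + float(np.linalg.slogdet(XtViX)[1]) + float(yv @ Py)
                 + (n - X.shape[1]) * np.log(2.0 * np.pi))
    # tr(P K_k) and y'P K_k P y for every component (K, then I)
    Vi = cho_solve(c, np.eye(n), check_finite=False)
    P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
    grads = []
    for K in [*Ks, np.eye(n)]:
        trPK = float(np.sum(P * K.T))
        yPKPy = float(Py @ (K @ Py))
        grads.append((trPK, yPKPy))
    return beta, Py, ll, grads


def multikernel_reml(
    y: pd.Series,
    kernels: list[LabeledMatrix],
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixedModelFit:
    """REML variance components for several kernels plus a residual.

    EM-REML iterations (guaranteed uphill, robust far from the optimum)
    followed by an L-BFGS polish of the restricted likelihood in
    log-variance coordinates.  GEBVs are the summed per-kernel BLUPs
    ``g_k = sigma_k^2 K_k P y``.  Numerically identical kernels trigger a
    warning: only their summed variance is identifiable.
    """
    if len(kernels) < 1:
        raise ValidationError("need at least one kernel")
    y = pd.Series(y).dropna()
    labels = [str(l) for l in y.index]
    Ks = []
    for k in kernels:
        missing = [l for l in labels if l not in k.index]
        if missing:
            raise ValidationError(f"phenotyped genotypes missing from kernel: {missing[:5]}")
        Ks.append(k.submatrix(labels).values)
    for i in range(len(Ks)):
        for j in range(i + 1, len(Ks)):
            denom = max(np.linalg.norm(Ks[i]), 1e-30)
            if np.linalg.norm(Ks[i] - Ks[j]) / denom < 1e-9:
                warnings.warn(
                    f"kernels {i} and {j} are numerically identical; only the "
                    "sum of their variance components is identifiable"
                )
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    if n < 3:
        raise ValidationError(f"need at least 3 phenotyped genotypes, got {n}")
    X = np.ones((n, 1))
    vary = float(np.var(yv))
    if vary < 1e-14:
        zeros = np.zeros(len(Ks) + 1)
        return MixedModelFit(zeros, np.array([float(np.mean(yv))]),
                             pd.Series(np.zeros(n), index=labels), 0.0,
                             method="multikernel_reml")
    nc = len(Ks) + 1
    s2 = np.full(nc, vary / nc)
    floor = 1e-10 * vary

    converged = False
    for _ in range(max_iter):
        _, Py, ll, grads = _reml_pieces(yv, X, Ks, s2)
        new = np.empty_like(s2)
        for k, (trPK, yPKPy) in enumerate(grads):
            new[k] = s2[k] + (s2[k] ** 2 / n) * (yPKPy - trPK)
        new = np.clip(new, floor, None)
        if np.max(np.abs(new - s2)) < tol * max(vary, 1e-30):
            s2 = new
            converged = True
            break
        s2 = new

    # quasi-Newton polish on theta = log(s2)
    def nll(theta):
        s = np.exp(theta)
        _, _, ll, grads = _reml_pieces(yv, X, Ks, s)
        g = np.array([-0.5 * (yPKPy - trPK) * sk
                      for sk, (trPK, yPKPy) in zip(s, grads)])
        return -ll, g

    res = optimize.minimize(nll, np.log(np.clip(s2, floor, None)), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10})
    s2 = np.exp(res.x)
    s2[s2 < 10 * floor] = 0.0
    s2 = np.clip(s2, 1e-12 * vary, None)  # keep V invertible
    beta, Py, ll, _ = _reml_pieces(yv, X, Ks, s2)
    per_kernel = [pd.Series(sk * (K @ Py), index=labels)
                  for sk, K in zip(s2[:-1], Ks)]
    total = sum(per_kernel) if per_kernel else pd.Series(np.zeros(n), index=labels)
    s2_out = np.where(s2 <= 1e-11 * vary, 0.0, s2)
    gvar = float(np.sum(s2_out[:-1]))
    return MixedModelFit(
        var_components=s2_out,
        fixed_effects=np.asarray(beta, dtype=float).ravel(),
        genotype_effects=total,
        h2=gvar / (gvar + s2_out[-1]) if gvar + s2_out[-1] > 0 else 0.0,
        loglik=float(ll), converged=converged or res.success,
        method="multikernel_reml", per_kernel_effects=per_kernel,
    )


class MultiKernelGBLUP:
    """Multi-kernel BLUP model: ``MultiKernelGBLUP(y, [K1, K2]).fit()``."""

    def __init__(self, y: pd.Series, kernels: list[LabeledMatrix]):
        self.y = pd.Series(y)
        self.kernels = list(kernels)

    def fit(self, **kwargs) -> MixedModelFit:
        return multikernel_reml(self.y, self.kernels, **kwargs)

    def predict(self, fit: MixedModelFit, test_labels) -> pd.Series:
        """Sum of per-kernel conditional-mean predictions."""
        if fit.per_kernel_effects is None:
            return gblup_predict(fit, self.kernels[0], test_labels)
        total = None
        for k, eff in zip(self.kernels, fit.per_kernel_effects):
            sub = MixedModelFit(
                var_components=fit.var_components[[0, -1]],
                fixed_effects=fit.fixed_effects, genotype_effects=eff,
                h2=fit.h2, method=fit.method,
            )
            p = gblup_predict(sub, k, test_labels)
            total = p if total is None else total + p
        return total


# ---------------------------------------------------------------------------
# cross-validation harnesses
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-group prediction accuracies plus the pooled accuracy."""

    table: pd.DataFrame
    pooled_accuracy: float
    predictions: pd.Series = field(repr=False, default=None)

    def summary(self) -> str:
        lines = ["Cross-validation accuracy", "=" * 30,
                 self.table.to_string(index=False),
                 f"pooled accuracy: {self.pooled_accuracy:.4f}"]
        return "\n".join(lines)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or float(np.std(a)) == 0.0 or float(np.std(b)) == 0.0:
        warnings.warn("degenerate (constant) vector in accuracy; reporting 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cv_random_folds(
    y: pd.Series, k: LabeledMatrix, n_folds: int = 10, seed: int = 0
) -> CVResult:
    """Random-split cross-validation of G-BLUP accuracy.

    Genotypes are partitioned into ``n_folds`` disjoint folds by the seeded
    RNG; for each fold the model is refitted on the remainder and the
    fold's GEBVs are correlated with its observed phenotypes.  The pooled
    accuracy correlates all out-of-fold predictions at once.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    y = pd.Series(y).dropna()
    labels = np.array([str(l) for l in y.index])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labels))
    folds = np.array_split(perm, n_folds)
    if min(len(f) for f in folds) < 3:
        raise ValidationError(
            f"{len(labels)} genotypes in {n_folds} folds leaves a fold with < 3"
        )
    rows = []
    preds = {}
    for fi, f in enumerate(folds):
        test = list(labels[f])
        train_y = y.drop(index=test)
        fit = reml_spectral(train_y, k)
        p = gblup_predict(fit, k, test)
        for lab, v in p.items():
            preds[lab] = v
        rows.append({
            "fold": fi, "n_test": len(test),
            "accuracy": _safe_corr(p.to_numpy(), y.loc[test].to_numpy()),
        })
    pred_series = pd.Series(preds).loc[list(labels)]
    pooled = _safe_corr(pred_series.to_numpy(), y.loc[pred_series.index].to_numpy())
    return CVResult(pd.DataFrame(rows), pooled, pred_series)


def cv_leave_dataset_out(
    y: pd.Series, k: LabeledMatrix, membership: dict[str, str]
) -> CVResult:
    """Leave-one-dataset-out cross-validation.

    ``membership`` maps each genotype to its dataset.  For each dataset the
    model trains on all other genotypes and predicts the held-out set;
    accuracy is the within-dataset correlation.  Datasets with no observed
    phenotypes are skipped with a warning.
    """
    y = pd.Series(y).dropna()
    labels = [str(l) for l in y.index]
    datasets = sorted({membership[l] for l in labels if l in membership})
    if len(datasets) < 2:
        raise ValidationError("need >= 2 datasets with phenotyped genotypes")
    rows = []
    preds = {}
    for d in datasets:
        test = [l for l in labels if membership.get(l) == d]
        if not test:
            warnings.warn(f"dataset {d!r} has no phenotyped genotypes; skipped")
            continue
        train_y = y.drop(index=test)
        if len(train_y) < 3:
            warnings.warn(f"dataset {d!r} leaves < 3 training genotypes; skipped")
            continue
        fit = reml_spectral(train_y, k)
        p = gblup_predict(fit, k, test)
        for lab, v in p.items():
            preds[lab] = v
        rows.append({
            "dataset": d, "n_test": len(test),
            "accuracy": _safe_corr(p.to_numpy(), y.loc[test].to_numpy()),
        })
    pred_series = pd.Series(preds)
    pooled = _safe_corr(pred_series.to_numpy(), y.loc[pred_series.index].to_numpy())
    return CVResult(pd.DataFrame(rows), pooled, pred_series)
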