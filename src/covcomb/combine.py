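"""Wishart EM estimation of a combined relationship matrix from partial samples.

The model
---------
Let ``K`` be the union of ``m`` partially overlapping genotype subsets
``a_1, ..., a_m`` and let ``G_a`` be the relationship (covariance) matrix
observed on subset ``a``.  Each observed matrix is modeled as an
independent Wishart draw

    ``G_a ~ W(nu, Psi_a)``   with   ``E[G_a] = nu * Psi_a = Sigma_a``,

where ``Sigma = nu * Psi`` is the combined relationship matrix over all of
``K`` and ``Sigma_a`` its restriction to ``a``.  The degrees of freedom
``nu`` play the role of the effective number of features (markers,
transcripts, records) behind each partial matrix.

The EM iteration completes each sample to the full ``K x K`` matrix using
the conditional moments of the Wishart/Gaussian model — with ``b = K \\ a``,

    ``B = Psi_ba Psi_a^{-1}``          (regression of b on a)
    ``Psi_{b|a} = Psi_b - Psi_ba Psi_a^{-1} Psi_ab``

the completion is ``[[G_a, G_a B'], [B G_a, nu*Psi_{b|a} + B G_a B']]`` —
and averages the completions:

    ``Psi^(t+1) = (1/(nu*m)) * sum_a P_a [completion] P_a'``.

The estimate is ``Sigma^(T) = nu * Psi^(T)``.  The choice of ``nu`` does
not affect the estimate (only the curvature of the likelihood); this
invariance is exact in the algebra and is asserted by the test-suite.

A weighted variant replaces ``G_a`` by ``w_a G_a + (1 - w_a) nu Psi_a^(t)``
each iteration, shrinking unreliable samples toward the current model.

When ``Sigma^(0)`` is a full pedigree matrix ``A`` and a single genomic
``G`` nested in it is supplied, one iteration reproduces the single-step
H-matrix blend exactly (:func:`hmatrix_oracle` is the closed form); the EM
generalizes that construction to any number of non-nested samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import multigammaln

from .io_core import (
    LabeledMatrix,
    NumericalError,
    PartialSample,
    ValidationError,
    union_align,
)

__all__ = [
    "EMConfig",
    "CombineResult",
    "CovarianceCombiner",
    "conditional_blocks",
    "expected_completion",
    "blend_weighted",
    "em_update",
    "wishart_loglik",
    "combine_em",
    "hmatrix_oracle",
    "default_nu",
]

_LOG2 = float(np.log(2.0))


@dataclass
class EMConfig:
    """Tuning knobs for the Wishart EM.

    nu
        Wishart degrees of freedom.  ``None`` derives the default: the mean
        of the samples' ``n_features`` where recorded, else 1000 (any large
        value gives the same estimate).
    tol
        Convergence threshold on the relative Frobenius change
        ``||Psi^(t+1) - Psi^(t)||_F / ||Psi^(t)||_F``.
    max_iter
        Iteration cap; non-convergence returns a result flagged
        ``converged=False`` with a warning.
    jitter
        Relative ridge used *on demand*: block Cholesky factorizations are
        attempted unregularized first and the ridge (``jitter`` times the
        mean block diagonal, escalating) is added only on failure.
    init
        ``"identity"`` (uninformative prior ``Sigma^(0) = I``) or a
        symmetric PD :class:`LabeledMatrix` covering the union of sample
        labels, encoding prior knowledge of the combined relationship.
    """

    nu: float | None = None
    tol: float = 1e-6
    max_iter: int = 200
    jitter: float = 1e-8
    init: str | LabeledMatrix = "identity"

    def __post_init__(self) -> None:
        if self.nu is not None and self.nu <= 0:
            raise ValidationError("nu must be positive")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.jitter < 0:
            raise ValidationError("jitter must be non-negative")


def default_nu(samples: list[PartialSample]) -> float:
    """Mean recorded feature count across samples, else 1000."""
    feats = [s.kernel.n_features for s in samples if s.kernel.n_features]
    return float(np.mean(feats)) if feats else 1000.0


# ---------------------------------------------------------------------------
# linear-algebra helpers
# ---------------------------------------------------------------------------

def _chol_with_escalating_jitter(M: np.ndarray, jitter: float, what: str):
    """Cholesky factor of ``M``, adding an escalating ridge only if needed."""
    scale = max(float(np.mean(np.diag(M))), np.finfo(float).tiny) if M.size else 1.0
    for eps in (0.0, jitter, jitter * 1e2, jitter * 1e4, 1e-6):
        try:
            A = M if eps == 0.0 else M + (eps * scale) * np.eye(M.shape[0])
            return cho_factor(A, lower=True, check_finite=False)
        except LinAlgError:
            continue
    raise NumericalError(f"{what}: block not positive definite even after jitter")


def _logdet_psd(M: np.ndarray, jitter: float = 1e-10) -> float:
    """log|M| for a PSD matrix, ridging singular inputs (escalating)."""
    sign, ld = np.linalg.slogdet(M)
    if sign > 0 and np.isfinite(ld):
        return float(ld)
    scale = max(float(np.mean(np.diag(M))), np.finfo(float).tiny)
    for eps in (jitter, jitter * 1e2, jitter * 1e4):
        sign, ld = np.linalg.slogdet(M + eps * scale * np.eye(M.shape[0]))
        if sign > 0 and np.isfinite(ld):
            return float(ld)
    raise NumericalError("log-determinant of a non-PSD matrix")


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------

def conditional_blocks(
    psi: LabeledMatrix, a: list[str], jitter: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Wishart/Gaussian conditional blocks of ``psi`` given subset ``a``.

    Returns ``(B, psi_b_given_a)`` with ``B = Psi_ba Psi_a^{-1}`` of shape
    ``|b| x |a|`` (regression coefficients of the unobserved set ``b`` on
    ``a``) and the conditional covariance
    ``Psi_{b|a} = Psi_b - Psi_ba Psi_a^{-1} Psi_ab`` (``|b| x |b|``).
    ``b`` is ``labels(psi) \\ a`` in psi's label order.  Degenerate case
    ``a == labels(psi)`` returns empty arrays.
    """
    idx = psi.index
    missing = [l for l in a if l not in idx]
    if missing:
        raise ValidationError(f"subset labels not in psi: {missing}")
    a_idx = np.array([idx[l] for l in a], dtype=int)
    in_a = np.zeros(psi.n, dtype=bool)
    in_a[a_idx] = True
    b_idx = np.where(~in_a)[0]
    Pa = psi.values[np.ix_(a_idx, a_idx)]
    if b_idx.size == 0:
        return np.empty((0, len(a))), np.empty((0, 0))
    try:
        c = _chol_with_escalating_jitter(Pa, jitter, "conditional_blocks")
    except NumericalError as exc:
        raise NumericalError(f"{exc}; subset labels {list(a)[:5]}...") from exc
    Pab = psi.values[np.ix_(a_idx, b_idx)]
    B = cho_solve(c, Pab, check_finite=False).T       # |b| x |a|
    Pbga = psi.values[np.ix_(b_idx, b_idx)] - B @ Pab
    return B, (Pbga + Pbga.T) / 2.0


def blend_weighted(sample: PartialSample, psi: LabeledMatrix, nu: float) -> np.ndarray:
    """Weighted observation ``w*G_a + (1-w)*nu*Psi_a`` on block ``a``.

    Returned in the sample's own label order; ``w=1`` is the raw kernel,
    ``w=0`` the model's current prediction of the block.
    """
    idx = psi.index
    a_idx = np.array([idx[l] for l in sample.labels], dtype=int)
    Pa = psi.values[np.ix_(a_idx, a_idx)]
    w = sample.weight
    return w * sample.kernel.values + (1.0 - w) * nu * Pa


def expected_completion(
    psi: LabeledMatrix, sample: PartialSample, nu: float, jitter: float = 1e-8
) -> np.ndarray:
    """Per-sample completed matrix, aligned to ``psi``'s label order.

    The ``a x a`` block is the (weighted) observation itself; the cross and
    unobserved blocks are its conditional expectations under the Wishart
    model: ``[[G_a, G_a B'], [B G_a, nu*Psi_{b|a} + B G_a B']]``.
    """
    idx = psi.index
    a_pos = np.array([idx[l] for l in sample.labels], dtype=int)
    order = np.argsort(a_pos)
    a_idx = a_pos[order]
    G = blend_weighted(sample, psi, nu)[np.ix_(order, order)]
    in_a = np.zeros(psi.n, dtype=bool)
    in_a[a_idx] = True
    b_idx = np.where(~in_a)[0]
    out = np.zeros((psi.n, psi.n))
    out[np.ix_(a_idx, a_idx)] = G
    if b_idx.size:
        B, Pbga = conditional_blocks(psi, [psi.labels[i] for i in a_idx], jitter)
        GBt = G @ B.T                                  # |a| x |b|
        out[np.ix_(a_idx, b_idx)] = GBt
        out[np.ix_(b_idx, a_idx)] = GBt.T
        out[np.ix_(b_idx, b_idx)] = nu * Pbga + B @ GBt
    return (out + out.T) / 2.0


def em_update(
    psi_t: LabeledMatrix, samples: list[PartialSample], nu: float, jitter: float = 1e-8
) -> LabeledMatrix:
    """One EM step: average of expected completions divided by ``nu``.

    ``Psi^(t+1) = (1/(nu*m)) * sum_a P_a [completion_a] P_a'`` with the
    alignment done through index maps.
    """
    if not samples:
        raise ValidationError("em_update requires at least one sample")
    acc = np.zeros((psi_t.n, psi_t.n))
    for s in samples:
        acc += expected_completion(psi_t, s, nu, jitter)
    acc /= nu * len(samples)
    return LabeledMatrix(list(psi_t.labels), acc, source="em_update")


def _wishart_logpdf(G: np.ndarray, logdet_G: float, Psi_chol, logdet_Psi: float,
                    nu: float) -> float:
    """log density of W(nu, Psi) at G, given precomputed factorizations."""
    p = G.shape[0]
    tr = float(np.trace(cho_solve(Psi_chol, G, check_finite=False)))
    return (
        0.5 * (nu - p - 1.0) * logdet_G
        - 0.5 * tr
        - 0.5 * nu * p * _LOG2
        - 0.5 * nu * logdet_Psi
        - multigammaln(0.5 * nu, p)
    )


def wishart_loglik(
    samples: list[PartialSample], psi: LabeledMatrix, nu: float, jitter: float = 1e-8
) -> float:
    """Sum of log Wishart densities ``log W(G_a; nu, Psi_a)`` over samples.

    Samples with ``nu <= |a| - 1`` (density undefined) are skipped with a
    warning; singular observed ``G_a`` (e.g. GRMs centered at observed
    allele frequencies) get a tiny ridge inside their log-determinant — a
    per-sample constant that cannot affect EM monotonicity.
    """
    idx = psi.index
    total = 0.0
    for s in samples:
        p = len(s.labels)
        if nu <= p - 1:
            warnings.warn(
                f"sample of size {p} skipped in log-likelihood: nu={nu} <= {p - 1}"
            )
            continue
        a_idx = np.array([idx[l] for l in s.labels], dtype=int)
        Pa = psi.values[np.ix_(a_idx, a_idx)]
        c = _chol_with_escalating_jitter(Pa, jitter, "wishart_loglik")
        logdet_Pa = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        G = s.kernel.values
        total += _wishart_logpdf(G, _logdet_psd(G), c, logdet_Pa, nu)
    return total


# ---------------------------------------------------------------------------
# results object + full algorithm
# ---------------------------------------------------------------------------

@dataclass
class CombineResult:
    """Fitted combined relationship matrix and diagnostics.

    Attributes
    ----------
    sigma
        The combined relationship estimate ``Sigma = nu * Psi^(T)`` over
        the sorted union of sample labels.
    nu
        Degrees of freedom used (does not affect ``sigma``).
    n_iter, converged
        EM iterations run and whether the relative-Frobenius criterion was
        met before ``max_iter``.
    loglik_trace
        Observed-data log-likelihood at each visited iterate (including the
        final one); non-decreasing by the EM ascent property.
    observed_mask
        Boolean ``n x n`` matrix, ``True`` where the entry was observed in
        at least one partial sample.
    """

    sigma: LabeledMatrix
    nu: float
    n_iter: int
    loglik_trace: list[float]
    converged: bool
    observed_mask: np.ndarray
    deltas: list[float] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return self.sigma.labels

    @property
    def psi(self) -> np.ndarray:
        return self.sigma.values / self.nu

    def summary(self) -> str:
        n = self.sigma.n
        obs = int(np.triu(self.observed_mask).sum())
        tot = n * (n + 1) // 2
        lines = [
            "Wishart EM combined relationship estimate",
            "=" * 45,
            f"genotypes (union)        : {n}",
            f"degrees of freedom (nu)  : {self.nu:g}",
            f"iterations               : {self.n_iter}"
            + ("" if self.converged else "  (NOT converged)"),
            f"final log-likelihood     : {self.loglik_trace[-1]:.4f}"
            if self.loglik_trace else "final log-likelihood     : n/a",
            f"observed entries         : {obs}/{tot} "
            f"({100.0 * obs / tot:.1f}% of upper triangle)",
            f"last relative change     : "
            + (f"{self.deltas[-1]:.3e}" if self.deltas else "n/a"),
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Log-likelihood trace plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(len(self.loglik_trace)), self.loglik_trace, marker=".")
        ax.set_xlabel("EM iteration")
        ax.set_ylabel("log-likelihood")
        return ax


class CovarianceCombiner:
    """Model object for the Wishart EM combiner.

    Parameters
    ----------
    samples
        Partial relationship matrices (:class:`PartialSample` or bare
        :class:`LabeledMatrix`, which get weight 1).
    config
        Optional :class:`EMConfig`; keyword arguments override its fields.

    ``fit()`` returns a :class:`CombineResult`.
    """

    def __init__(self, samples, config: EMConfig | None = None, **kwargs):
        self.samples = [
            s if isinstance(s, PartialSample) else PartialSample(s) for s in samples
        ]
        if not self.samples:
            raise ValidationError("need at least one partial sample")
        cfg = config or EMConfig()
        if kwargs:
            cfg = EMConfig(**{**cfg.__dict__, **kwargs})
        self.config = cfg
        union, _ = union_align(self.samples)
        if isinstance(cfg.init, LabeledMatrix):
            # genotypes carried only by the prior matrix stay in the union:
            # their blocks are completed by conditioning on the observed sets
            # (the single-step H-matrix construction relies on exactly this)
            union = sorted(set(union) | set(cfg.init.labels))
        self.union_labels = union
        pos = {lab: i for i, lab in enumerate(union)}
        self.index_maps = [
            np.array([pos[l] for l in s.labels], dtype=int) for s in self.samples
        ]

    # -- internal: prepared per-sample data ---------------------------------
    def _prepare(self):
        prepped = []
        for s, amap in zip(self.samples, self.index_maps):
            order = np.argsort(amap)
            a_idx = amap[order]
            G = s.kernel.values[np.ix_(order, order)]
            prepped.append((a_idx, G, s.weight, _logdet_psd(G)))
        return prepped

    def _initial_sigma(self) -> np.ndarray:
        K = self.union_labels
        init = self.config.init
        if isinstance(init, str):
            if init != "identity":
                raise ValidationError(f"unknown init {init!r}")
            return np.eye(len(K))
        missing = [l for l in K if l not in init.index]
        if missing:
            raise ValidationError(
                f"init matrix does not cover union labels, missing {missing[:5]}"
            )
        S0 = init.submatrix(K).values
        w = np.linalg.eigvalsh(S0)
        if w[0] <= 0:
            raise ValidationError(
                "init matrix must be symmetric positive definite "
                f"(min eigenvalue {w[0]:.3g}); consider kernels.ensure_psd"
            )
        return S0

    def fit(self) -> CombineResult:
        cfg = self.config
        nu = cfg.nu if cfg.nu is not None else default_nu(self.samples)
        K = self.union_labels
        n = len(K)
        prepped = self._prepare()
        psi = self._initial_sigma() / nu

        # warn once for samples the likelihood cannot score
        ll_ok = []
        for a_idx, G, w, ldG in prepped:
            ok = nu > len(a_idx) - 1
            if not ok:
                warnings.warn(
                    f"sample of size {len(a_idx)} skipped in log-likelihood trace: "
                    f"nu={nu} <= {len(a_idx) - 1}"
                )
            ll_ok.append(ok)

        trace: list[float] = []
        deltas: list[float] = []
        converged = False
        n_iter = 0
        for _ in range(cfg.max_iter):
            psi_next, ll = self._step(psi, prepped, nu, ll_ok)
            trace.append(ll)
            norm = np.linalg.norm(psi)
            delta = np.linalg.norm(psi_next - psi) / (norm if norm > 0 else 1.0)
            deltas.append(delta)
            psi = psi_next
            n_iter += 1
            if delta < cfg.tol:
                converged = True
                break
        # likelihood at the final iterate
        _, ll = self._step(psi, prepped, nu, ll_ok, update=False)
        trace.append(ll)
        if not converged:
            warnings.warn(
                f"Wishart EM did not converge in {cfg.max_iter} iterations "
                f"(last relative change {deltas[-1]:.3e})"
            )

        mask = np.zeros((n, n), dtype=bool)
        for a_idx, *_ in prepped:
            mask[np.ix_(a_idx, a_idx)] = True
        sigma = LabeledMatrix(list(K), nu * (psi + psi.T) / 2.0,
                              source="combine_em")
        return CombineResult(
            sigma=sigma, nu=float(nu), n_iter=n_iter, loglik_trace=trace,
            converged=converged, observed_mask=mask, deltas=deltas,
        )

    def _step(self, psi: np.ndarray, prepped, nu: float, ll_ok,
              update: bool = True):
        """Fused E+M step and log-likelihood, sharing block factorizations."""
        jitter = self.config.jitter
        n = psi.shape[0]
        acc = np.zeros((n, n)) if update else None
        ll = 0.0
        for (a_idx, G, w, ldG), ok in zip(prepped, ll_ok):
            Pa = psi[np.ix_(a_idx, a_idx)]
            c = _chol_with_escalating_jitter(Pa, jitter, "em step")
            if ok:
                logdet_Pa = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
                ll += _wishart_logpdf(G, ldG, c, logdet_Pa, nu)
            if not update:
                continue
            Gw = G if w == 1.0 else w * G + (1.0 - w) * nu * Pa
            in_a = np.zeros(n, dtype=bool)
            in_a[a_idx] = True
            b_idx = np.where(~in_a)[0]
            acc[np.ix_(a_idx, a_idx)] += Gw
            if b_idx.size:
                Pab = psi[np.ix_(a_idx, b_idx)]
                B = cho_solve(c, Pab, check_finite=False).T     # |b| x |a|
                Pbga = psi[np.ix_(b_idx, b_idx)] - B @ Pab
                GBt = Gw @ B.T
                acc[np.ix_(a_idx, b_idx)] += GBt
                acc[np.ix_(b_idx, a_idx)] += GBt.T
                acc[np.ix_(b_idx, b_idx)] += nu * Pbga + B @ GBt
        if not update:
            return psi, ll
        acc /= nu * len(prepped)
        return (acc + acc.T) / 2.0, ll


def combine_em(samples, config: EMConfig | None = None, **kwargs) -> CombineResult:
    """Combine partial relationship matrices by the Wishart EM algorithm.

    Functional front-end for :class:`CovarianceCombiner`; see the module
    docstring for the model.  ``samples`` may be :class:`PartialSample`
    objects or bare :class:`LabeledMatrix` kernels (weight 1).
    """
    return CovarianceCombiner(samples, config, **kwargs).fit()


def hmatrix_oracle(a_full: LabeledMatrix, g_nested: LabeledMatrix) -> LabeledMatrix:
    """Closed-form single-step H-matrix blending ``A`` with a nested ``G``.

    With index 2 the genotyped set (labels of ``g_nested``) and 1 the rest:

    ``H_22 = G``;  ``H_12 = A_12 A_22^{-1} G``;
    ``H_11 = A_11 + A_12 A_22^{-1} (G - A_22) A_22^{-1} A_21``.

    Output labels follow ``a_full``.  One EM iteration started at
    ``Sigma^(0) = A`` with the single sample ``G`` reproduces this matrix.
    """
    setA = set(a_full.labels)
    missing = [l for l in g_nested.labels if l not in setA]
    if missing:
        raise ValidationError(f"G labels not nested in A: {missing[:5]}")
    idx = a_full.index
    i2 = np.array([idx[l] for l in g_nested.labels], dtype=int)
    in2 = np.zeros(a_full.n, dtype=bool)
    in2[i2] = True
    i1 = np.where(~in2)[0]
    A = a_full.values
    G = g_nested.values
    A22 = A[np.ix_(i2, i2)]
    try:
        A22_inv_G = np.linalg.solve(A22, G)
        A22_inv_A21 = np.linalg.solve(A22, A[np.ix_(i2, i1)])
    except np.linalg.LinAlgError as exc:
        raise NumericalError("A_22 is singular in hmatrix_oracle") from exc
    H = np.array(A, dtype=float, copy=True)
    H[np.ix_(i2, i2)] = G
    H12 = A[np.ix_(i1, i2)] @ A22_inv_G          # A12 A22^{-1} G, |1| x |2|
    H[np.ix_(i1, i2)] = H12
    H[np.ix_(i2, i1)] = H12.T
    H[np.ix_(i1, i1)] = (
        A[np.ix_(i1, i1)]
        + A22_inv_A21.T @ (G - A22) @ A22_inv_A21
    )
    return LabeledMatrix(list(a_full.labels), (H + H.T) / 2.0, source="hmatrix")
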