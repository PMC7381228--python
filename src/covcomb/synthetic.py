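"""Synthetic-data generators with the statistical structure the combiner assumes.

These generators emulate the study designs the package is validated on:

* independent-locus marker panels (binomial dosages at Hardy-Weinberg),
* multi-generation pedigrees with Mendelian gene-drop genotypes,
* overlapping genotype subsets carrying per-subset marker panels
  (the "many small heterogeneous panels" design),
* exact Wishart draws of partial relationship matrices from a known
  ground-truth covariance, and
* additive-plus-noise phenotypes at a chosen heritability.

They deliberately omit linkage disequilibrium, genetic maps and selection:
none of the properties asserted about the combiner depend on them.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import (
    LabeledMatrix,
    MarkerMatrix,
    PartialSample,
    Pedigree,
    ValidationError,
)

__all__ = [
    "OverlapDesign",
    "simulate_markers",
    "simulate_structured_markers",
    "simulate_pedigree_genedrop",
    "sample_wishart_partials",
    "make_overlap_design",
    "random_overlap_design",
    "simulate_phenotypes",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _labels(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


@dataclass
class OverlapDesign:
    """Which genotypes each partial sample covers.

    ``subsets`` is a list of label lists whose union must equal ``labels``
    (every genotype observed at least once); ``feature_counts`` optionally
    records how many features back each subset's kernel.
    """

    labels: list[str]
    subsets: list[list[str]]
    feature_counts: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.subsets:
            raise ValidationError("design needs at least one subset")
        full = set(self.labels)
        cov: set[str] = set()
        for s in self.subsets:
            if not s:
                raise ValidationError("empty subset in design")
            extra = set(s) - full
            if extra:
                raise ValidationError(f"subset labels outside design: {sorted(extra)[:5]}")
            cov |= set(s)
        if cov != full:
            raise ValidationError(
                f"subsets do not cover all labels ({len(full) - len(cov)} uncovered)"
            )
        if self.feature_counts is not None and len(self.feature_counts) != len(self.subsets):
            raise ValidationError("feature_counts length must match subsets")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def m(self) -> int:
        return len(self.subsets)


def simulate_markers(
    n_genotypes: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed=None,
) -> MarkerMatrix:
    """Independent biallelic loci: dosages ~ Binomial(2, p_j), p_j ~ U(lo, hi)."""
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValidationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    dos = rng.binomial(2, p, size=(n_genotypes, n_markers)).astype(float)
    return MarkerMatrix(_labels("g", n_genotypes), _labels("m", n_markers), dos)


def simulate_structured_markers(
    n_genotypes: int,
    n_markers: int,
    n_subpops: int = 3,
    fst: float = 0.2,
    family_size: int = 1,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed=None,
) -> MarkerMatrix:
    """Marker panel from a structured population (Balding-Nichols model).

    Genotypes are split evenly across ``n_subpops`` subpopulations; each
    locus has an ancestral frequency ``p ~ U(maf_range)`` and per-subpop
    frequencies ``~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F = fst``, so
    the realized relationship matrix carries the block structure typical
    of diversity panels.  With ``family_size > 1`` the members of each
    subpopulation are additionally organized into full-sib families of
    that size (two Hardy-Weinberg parents per family, offspring by
    Mendelian sampling), giving the high-rank cryptic-relatedness
    component real panels carry on top of the subpopulation blocks.
    Loci are independent.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValidationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if not (0.0 < fst < 1.0):
        raise ValidationError("fst must be in (0, 1)")
    if n_subpops < 1 or family_size < 1:
        raise ValidationError("n_subpops and family_size must be >= 1")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    membership = np.arange(n_genotypes) % n_subpops
    dos = np.empty((n_genotypes, n_markers))
    for s in range(n_subpops):
        ps = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
        rowsel = np.where(membership == s)[0]
        if family_size == 1:
            dos[rowsel] = rng.binomial(2, ps, size=(len(rowsel), n_markers))
            continue
        done = 0
        while done < len(rowsel):
            fam = rowsel[done:done + family_size]
            sire = (rng.random((2, n_markers)) < ps).astype(np.int8)
            dam = (rng.random((2, n_markers)) < ps).astype(np.int8)
            for i in fam:
                from_s = sire[rng.integers(0, 2, n_markers), np.arange(n_markers)]
                from_d = dam[rng.integers(0, 2, n_markers), np.arange(n_markers)]
                dos[i] = from_s + from_d
            done += family_size
    return MarkerMatrix(_labels("g", n_genotypes), _labels("m", n_markers), dos)


def simulate_pedigree_genedrop(
    n_founders: int,
    n_generations: int,
    offspring_per_cross: int,
    n_markers: int,
    seed=None,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[Pedigree, MarkerMatrix]:
    """Random-mating pedigree with genotypes by Mendelian gene drop.

    Founders are drawn in Hardy-Weinberg proportions at independent loci
    with allele frequencies uniform on ``maf_range``.  Each generation the
    previous generation is randomly paired into ``n_prev // 2`` crosses,
    each producing ``offspring_per_cross`` offspring; every offspring
    inherits one uniformly chosen parental allele per locus.

    Returns the full pedigree (founders included) and the dosage matrix of
    every individual; the true per-locus allele frequencies are attached to
    the marker matrix as ``founder_freqs`` for oracle computations that
    need unbiased centering.
    """
    if n_founders < 2 or n_founders % 2:
        raise ValidationError("n_founders must be an even integer >= 2")
    if n_generations < 1 or offspring_per_cross < 1:
        raise ValidationError("need n_generations >= 1 and offspring_per_cross >= 1")
    rng = _rng(seed)
    p = rng.uniform(*maf_range, size=n_markers)

    names: list[str] = []
    records: list[tuple[str, str, str]] = []
    hap0: list[np.ndarray] = []
    hap1: list[np.ndarray] = []

    def new_id() -> str:
        name = f"i{len(names):05d}"
        names.append(name)
        return name

    current: list[int] = []
    for _ in range(n_founders):
        gid = new_id()
        records.append((gid, "0", "0"))
        hap0.append((rng.random(n_markers) < p).astype(np.int8))
        hap1.append((rng.random(n_markers) < p).astype(np.int8))
        current.append(len(names) - 1)

    for _ in range(n_generations):
        parents = np.array(current)
        rng.shuffle(parents)
        nxt: list[int] = []
        for c in range(len(parents) // 2):
            sire, dam = int(parents[2 * c]), int(parents[2 * c + 1])
            for _ in range(offspring_per_cross):
                gid = new_id()
                records.append((gid, names[sire], names[dam]))
                pick_s = rng.integers(0, 2, n_markers)
                pick_d = rng.integers(0, 2, n_markers)
                hap0.append(np.where(pick_s == 0, hap0[sire], hap1[sire]))
                hap1.append(np.where(pick_d == 0, hap0[dam], hap1[dam]))
                nxt.append(len(names) - 1)
        current = nxt

    dosages = (np.array(hap0, dtype=np.int8) + np.array(hap1, dtype=np.int8)).astype(float)
    ped = Pedigree(records)
    # reorder marker rows to the pedigree's (topologically sorted) id order
    pos = {name: j for j, name in enumerate(names)}
    order = [pos[i] for i in ped.ids]
    mm = MarkerMatrix(ped.ids, _labels("m", n_markers), dosages[order])
    mm.founder_freqs = p
    return ped, mm


def make_overlap_design(
    n: int, m: int, subset_size: int, overlap_fraction: float, seed=None
) -> OverlapDesign:
    """Chain design: ``m`` subsets, consecutive ones sharing a fixed overlap.

    Subsets of ``subset_size`` labels are laid along a (seed-shuffled)
    ordering of ``n`` labels so that adjacent subsets share
    ``ceil(overlap_fraction * subset_size)`` labels; the last subset is
    padded with any labels the chain leaves uncovered so the union is all
    of ``n``.  Infeasible parameter combinations (chain runs off the end)
    raise with an explanation.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValidationError("overlap_fraction must be in [0, 1]")
    if subset_size < 1 or subset_size > n:
        raise ValidationError(f"subset_size {subset_size} not in [1, {n}]")
    k = int(np.ceil(overlap_fraction * subset_size))
    shift = subset_size - k
    last_start = (m - 1) * shift
    if last_start + subset_size > n:
        raise ValidationError(
            f"infeasible chain: {m} subsets of {subset_size} with shift {shift} "
            f"need {last_start + subset_size} labels but n={n}; reduce m, the "
            "subset size, or the overlap"
        )
    labels = _labels("g", n)
    order = list(labels)
    if seed is not None:
        _rng(seed).shuffle(order)
    subsets = [order[i * shift: i * shift + subset_size] for i in range(m)]
    tail = order[last_start + subset_size:]
    if tail:
        subsets[-1] = subsets[-1] + tail
    return OverlapDesign(labels, subsets)


def random_overlap_design(n: int, m: int, subset_size: int, seed=None) -> OverlapDesign:
    """``m`` uniformly random subsets of fixed size, patched to cover all ``n``.

    This is the "randomly sampled genotypes per panel" design: subsets are
    drawn independently; any label covered by no subset is appended to a
    random subset so the union constraint holds.
    """
    if subset_size < 1 or subset_size > n:
        raise ValidationError(f"subset_size {subset_size} not in [1, {n}]")
    rng = _rng(seed)
    labels = _labels("g", n)
    subsets = [list(rng.choice(labels, size=subset_size, replace=False)) for _ in range(m)]
    covered = set().union(*map(set, subsets))
    for lab in labels:
        if lab not in covered:
            subsets[int(rng.integers(m))].append(lab)
    return OverlapDesign(labels, subsets)


def sample_wishart_partials(
    sigma: LabeledMatrix, nu: float, design: OverlapDesign, seed=None
) -> list[PartialSample]:
    """Draw one Wishart partial sample per design subset from a known Sigma.

    Each subset ``a`` receives an independent ``G_a ~ W(nu, Sigma_a / nu)``
    so that ``E[G_a] = Sigma_a``.  Because marginal blocks of a Wishart are
    themselves Wishart, drawing the block directly is identical in
    distribution to drawing the full ``n x n`` matrix and restricting it.
    Sampling uses the Bartlett decomposition (scipy).
    """
    if set(design.labels) - set(sigma.labels):
        raise ValidationError("design labels must be labels of sigma")
    if nu <= sigma.n - 1:
        raise ValidationError(f"need nu > n - 1 = {sigma.n - 1}, got {nu}")
    w = np.linalg.eigvalsh(sigma.values)
    if w[0] <= 0:
        raise ValidationError(
            f"sigma must be positive definite (min eigenvalue {w[0]:.3g})"
        )
    rng = _rng(seed)
    out = []
    for i, a in enumerate(design.subsets):
        Sa = sigma.submatrix(a).values
        draw = stats.wishart.rvs(df=nu, scale=Sa / nu, random_state=rng)
        draw = np.atleast_2d(draw)
        nf = (design.feature_counts[i] if design.feature_counts is not None
              else int(round(nu)))
        out.append(PartialSample(LabeledMatrix(
            list(a), (draw + draw.T) / 2.0, source=f"wishart draw {i}", n_features=nf
        )))
    return out


def simulate_phenotypes(k: LabeledMatrix, h2: float, seed=None) -> "pd.Series":
    """Additive-plus-noise trait: ``y = g + e`` at heritability ``h2``.

    ``g ~ N(0, h2 * K_std)`` with ``K_std`` the kernel rescaled to mean
    diagonal 1, and ``e ~ N(0, (1 - h2) * I)``; so ``var(g)/var(y) ~ h2``.
    Returns a pandas Series indexed by the kernel labels.
    """
    import pandas as pd

    if not (0.0 <= h2 <= 1.0):
        raise ValidationError("h2 must be in [0, 1]")
    rng = _rng(seed)
    n = k.n
    d = float(np.mean(np.diag(k.values)))
    if d <= 0:
        raise ValidationError("kernel has non-positive mean diagonal")
    Ks = k.values / d
    # Cholesky of the jittered standardized kernel (PSD inputs expected)
    w = np.linalg.eigvalsh(Ks)
    eps = max(0.0, -float(w[0])) + 1e-10
    L = np.linalg.cholesky(Ks + eps * np.eye(n))
    g = np.sqrt(h2) * (L @ rng.standard_normal(n)) if h2 > 0 else np.zeros(n)
    e = np.sqrt(1.0 - h2) * rng.standard_normal(n) if h2 < 1 else np.zeros(n)
    return pd.Series(g + e, index=list(k.labels), name="y")
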