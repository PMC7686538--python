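"""Conventional population-genetics baselines: LD pruning, Fst, DAPC.

Fst uses Weir–Cockerham variance components combined across loci as a ratio
of sums (sum of among-population components over sum of total components).
Diploid sites use the three-component decomposition with the heterozygosity
term; haploid (mitochondrial) sites use the two-component haploid form.
Significance comes from label permutations with the standard
``(b + 1) / (n_perm + 1)`` empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .genotype_io import GenotypeBlock, PopulationPanel


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(a, b) -> float:
    """Squared Pearson correlation of two allele-dosage vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic site in LD computation")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune_ld(
    block: GenotypeBlock,
    window: int = 50,
    step: int = 10,
    threshold: float = 0.1,
) -> GenotypeBlock:
    """Sliding-window greedy LD pruning.

    Within each window of ``window`` contiguous (still-kept) original sites a
    greedy pass over pairs in position order removes the later site of any
    pair with r² above ``threshold``; the window then advances by ``step``
    sites. Removed sites stay removed. The result is a subset of the input
    sites and the operation is idempotent at fixed parameters.
    """
    n = block.n_sites
    if n == 0:
        return block
    dos = block.dosage().astype(float)
    # precomputable pieces of pairwise correlation
    mean = dos.mean(axis=0)
    centered = dos - mean
    norms = np.sqrt((centered**2).sum(axis=0))
    removed = np.zeros(n, dtype=bool)
    start = 0
    while start < n:
        idx = [i for i in range(start, min(start + window, n)) if not removed[i]]
        for ii, i in enumerate(idx):
            if removed[i]:
                continue
            for j in idx[ii + 1 :]:
                if removed[j]:
                    continue
                if norms[i] == 0 or norms[j] == 0:
                    continue
                r = centered[:, i] @ centered[:, j] / (norms[i] * norms[j])
                if r * r > threshold:
                    removed[j] = True
        start += step
    return block.subset_sites(np.flatnonzero(~removed))


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst


def _wc_components(states_a, states_b, diploid: bool):
    """Per-site Weir–Cockerham (a, b, c) component arrays for two samples.

    ``states_x`` is a (subjects, sites) state matrix for one population:
    haploid alleles {0,1} or diploid genotypes {0,1,2}.
    """
    r = 2
    n1 = float(states_a.shape[0])
    n2 = float(states_b.shape[0])
    if diploid:
        p1 = states_a.mean(axis=0) / 2.0
        p2 = states_b.mean(axis=0) / 2.0
        h1 = (states_a == 1).mean(axis=0)
        h2 = (states_b == 1).mean(axis=0)
    else:
        p1 = states_a.mean(axis=0)
        p2 = states_b.mean(axis=0)
        h1 = h2 = np.zeros_like(p1)
    n_tot = n1 + n2
    nbar = n_tot / r
    if nbar <= 1:
        z = np.zeros_like(p1)
        return z, z, z
    nc = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / n_tot
    pq = pbar * (1.0 - pbar)
    if diploid:
        a = (nbar / nc) * (
            s2 - (pq - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pq - (r - 1) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    else:
        a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pq - (r - 1) / r * s2)
        c = np.zeros_like(a)
    return a, b, c


def _fst_from_states(states_a, states_b, diploid: bool) -> float | None:
    a, b, c = _wc_components(
        states_a.astype(float), states_b.astype(float), diploid
    )
    den = (a + b + c).sum()
    if den == 0.0:
        return None
    return float(a.sum() / den)


def fst(
    block: GenotypeBlock,
    panel: PopulationPanel,
    pop_a: str,
    pop_b: str,
) -> float | None:
    """Multi-locus pairwise Weir–Cockerham theta for one gene.

    Returns None when no site is polymorphic between the pair (statistic
    undefined). The estimator may be slightly negative for undifferentiated
    populations.
    """
    rows_a = [i for i, s in enumerate(block.subject_ids) if panel[s] == pop_a]
    rows_b = [i for i, s in enumerate(block.subject_ids) if panel[s] == pop_b]
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("each population needs >= 2 subjects")
    diploid = not block.region.is_mitochondrial
    return _fst_from_states(
        block.states[rows_a], block.states[rows_b], diploid
    )


@dataclass
class FstResult:
    gene: str
    pop_a: str
    pop_b: str
    theta: float
    perm_values: np.ndarray
    p_value: float

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("empirical p-value must lie in (0, 1]")


def fst_permutation_p(
    block: GenotypeBlock,
    panel: PopulationPanel,
    pop_a: str,
    pop_b: str,
    n_perm: int = 200,
    seed: int = 0,
) -> FstResult:
    """Permutation test for pairwise theta.

    Pooled subjects of the two populations are relabeled ``n_perm`` times
    preserving group sizes; p = (#{theta_perm >= theta_obs} + 1) / (n_perm + 1).
    """
    theta = fst(block, panel, pop_a, pop_b)
    if theta is None:
        raise ValueError(
            f"Fst undefined for {block.region.name} ({pop_a} vs {pop_b})"
        )
    rows_a = [i for i, s in enumerate(block.subject_ids) if panel[s] == pop_a]
    rows_b = [i for i, s in enumerate(block.subject_ids) if panel[s] == pop_b]
    pooled = np.array(rows_a + rows_b)
    n_a = len(rows_a)
    diploid = not block.region.is_mitochondrial
    rng = np.random.default_rng(seed)
    perm_values = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(pooled)
        v = _fst_from_states(
            block.states[perm[:n_a]], block.states[perm[n_a:]], diploid
        )
        perm_values[t] = -np.inf if v is None else v
    p = (np.sum(perm_values >= theta) + 1.0) / (n_perm + 1.0)
    return FstResult(block.region.name, pop_a, pop_b, theta, perm_values, float(p))


def fst_specificity(
    p_values: dict[frozenset, float], alpha: float = 0.05
) -> str:
    """Classify a gene from its three pairwise permutation p-values.

    Returns ``'all'`` when all three pairs are significant, ``'specific:P'``
    when exactly the two pairs involving P are significant, else ``'none'``.
    """
    if len(p_values) != 3:
        raise ValueError("need p-values for all three population pairs")
    pops = sorted({p for key in p_values for p in key})
    if len(pops) != 3:
        raise ValueError("p-values must cover three populations")
    sig = {key for key, p in p_values.items() if p < alpha}
    if len(sig) == 3:
        return "all"
    for p in pops:
        involving = {key for key in p_values if p in key}
        if sig == involving:
            return f"specific:{p}"
    return "none"


# ---------------------------------------------------------------------------
# DAPC


class DAPC(TransformerMixin, BaseEstimator):
    """Discriminant analysis of principal components.

    A PCA rotation retaining ``n_pca`` components (default: smallest number
    explaining >= 90% of the variance, capped at n_subjects / 3) followed by
    linear discriminant analysis on the retained components. With g groups at
    most g - 1 discriminant axes exist.
    """

    def __init__(self, n_pca: int | None = None, var_explained: float = 0.9):
        self.n_pca = n_pca
        self.var_explained = var_explained

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = X.shape[0]
        groups = np.unique(y)
        if n < len(groups):
            raise ValueError("fewer subjects than groups")
        if self.n_pca is not None and self.n_pca >= n:
            raise ValueError("n_pca must be smaller than the subject count")
        max_rank = min(n - 1, X.shape[1])
        pca = PCA(n_components=max_rank).fit(X)
        if self.n_pca is None:
            cum = np.cumsum(pca.explained_variance_ratio_)
            k = int(np.searchsorted(cum, self.var_explained) + 1)
            k = min(k, max(n // 3, 1), max_rank)
        else:
            k = min(self.n_pca, max_rank)
        self.n_pca_ = k
        self.pca_ = PCA(n_components=k).fit(X)
        pcs = self.pca_.transform(X)
        n_axes = min(len(groups) - 1, 2, k)
        import warnings as _warnings

        with _warnings.catch_warnings():
            # identical group means leave no usable discriminant direction;
            # LDA then emits divide warnings and returns fewer axes
            _warnings.simplefilter("ignore", RuntimeWarning)
            self.lda_ = LinearDiscriminantAnalysis(n_components=n_axes).fit(pcs, y)
            coords = self.lda_.transform(pcs)
        self.classes_ = self.lda_.classes_
        self.n_axes_ = coords.shape[1]
        self.centroids_ = {
            g: coords[y == g].mean(axis=0) for g in self.classes_
        }
        self.centroid_distances_ = {
            frozenset((a, b)): float(
                np.linalg.norm(self.centroids_[a] - self.centroids_[b])
            )
            for i, a in enumerate(self.classes_)
            for b in self.classes_[i + 1 :]
        }
        return self

    def transform(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.transform(self.pca_.transform(np.asarray(X, float)))


@dataclass
class DAPCResult:
    gene: str
    coords: pd.DataFrame  # subjects x discriminant axes
    centroids: dict[str, np.ndarray]
    centroid_distances: dict[frozenset, float]
    n_pca: int


def dapc(
    blocks,
    panel: PopulationPanel,
    n_pca: int | None = None,
) -> DAPCResult:
    """DAPC on one block or a list of blocks (dosage matrices concatenated)."""
    if isinstance(blocks, GenotypeBlock):
        blocks = [blocks]
    subjects = blocks[0].subject_ids
    for b in blocks:
        if b.subject_ids != subjects:
            raise ValueError("blocks disagree on subject ordering")
    X = np.column_stack([b.dosage() for b in blocks]).astype(float)
    y = panel.labels(subjects)
    est = DAPC(n_pca=n_pca).fit(X, y)
    coords = pd.DataFrame(
        est.transform(X),
        index=pd.Index(subjects, name="subject"),
        columns=[f"LD{i + 1}" for i in range(est.n_axes_)],
    )
    name = blocks[0].region.name if len(blocks) == 1 else "+".join(
        b.region.name for b in blocks
    )
    return DAPCResult(
        name, coords, est.centroids_, est.centroid_distances_, est.n_pca_
    )
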