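"""Reference-population frequency-score encodings.

For a designated *reference* population, each genotype state at each site has
an empirical reference frequency ``f_ref``. A subject's score for a gene is
the mean, over the gene's sites, of ``1 - f_ref(state the subject carries)``
— the mean rarity, in the reference population, of the subject's states. For
an (mt gene, nuc gene) pair the same construction runs over all mt x nuc site
pairs with the six joint states (mt allele x collapsed diploid genotype).
Scores always lie in [0, 1]: 0 when every carried state is fixed in the
reference, 1 when every carried state is unseen there.

The pair score over all site pairs admits a large reduction: the summed joint
reference frequency for subject ``s`` equals the average over reference
subjects ``r`` of (number of mt sites where s and r match) x (number of
nuclear sites where they match), so no per-site-pair table is ever
materialized. The encoders below are scikit-learn transformers: ``fit``
ingests the reference subjects' state matrix, ``transform`` scores any
subjects over the same sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .genotype_io import GenotypeBlock, PopulationPanel

JOINT_STATES = [(a, g) for a in (0, 1) for g in (0, 1, 2)]  # paper order


# ---------------------------------------------------------------------------
# frequency tables


@dataclass
class ReferenceFrequencyTable:
    """Per-site state frequencies in the reference population."""

    ref_pop: str
    site_ids: list[str]
    freqs: np.ndarray  # (n_sites, n_states), rows sum to 1

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.size and not np.allclose(self.freqs.sum(axis=1), 1.0):
            raise ValueError("state frequencies must sum to 1 per site")


@dataclass
class JointReferenceFrequencyTable:
    """Joint (mt allele, nuc genotype) frequencies for every site pair."""

    ref_pop: str
    mt_site_ids: list[str]
    nuc_site_ids: list[str]
    freqs: np.ndarray  # (n_mt, n_nuc, 6) in JOINT_STATES order

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.size and not np.allclose(self.freqs.sum(axis=2), 1.0):
            raise ValueError("joint frequencies must sum to 1 per site pair")


def _check_ref(block: GenotypeBlock, panel: PopulationPanel, ref_pop: str):
    if ref_pop not in panel.populations:
        raise ValueError(f"reference population {ref_pop!r} absent from panel")
    rows = [i for i, s in enumerate(block.subject_ids) if panel[s] == ref_pop]
    if not rows:
        raise ValueError(f"no subjects of {ref_pop!r} in block {block.region.name}")
    return np.array(rows)


def reference_frequencies(
    block: GenotypeBlock, panel: PopulationPanel, ref_pop: str
) -> ReferenceFrequencyTable:
    """Empirical per-site state frequencies over reference subjects only."""
    rows = _check_ref(block, panel, ref_pop)
    sub = block.states[rows]
    n_states = block.n_states
    freqs = np.stack(
        [(sub == k).mean(axis=0) for k in range(n_states)], axis=1
    )
    return ReferenceFrequencyTable(ref_pop, [s.site_id for s in block.sites], freqs)


def joint_reference_frequencies(
    mt_block: GenotypeBlock,
    nuc_block: GenotypeBlock,
    panel: PopulationPanel,
    ref_pop: str,
) -> JointReferenceFrequencyTable:
    """Joint 6-state frequencies for all (mt site, nuc site) pairs."""
    if mt_block.subject_ids != nuc_block.subject_ids:
        raise ValueError("mt and nuc blocks must share one subject ordering")
    rows = _check_ref(mt_block, panel, ref_pop)
    A = mt_block.states[rows]  # (r, m)
    G = nuc_block.states[rows]  # (r, k)
    n_ref = len(rows)
    freqs = np.empty((mt_block.n_sites, nuc_block.n_sites, 6))
    for idx, (a, g) in enumerate(JOINT_STATES):
        freqs[:, :, idx] = (A == a).T.astype(float) @ (G == g) / n_ref
    return JointReferenceFrequencyTable(
        ref_pop,
        [s.site_id for s in mt_block.sites],
        [s.site_id for s in nuc_block.sites],
        freqs,
    )


# ---------------------------------------------------------------------------
# single-subject scores (reference operations; the encoders vectorize these)


def gene_score(
    block: GenotypeBlock, ref_table: ReferenceFrequencyTable, subject: str
) -> float:
    """Mean reference rarity of one subject's states in one gene."""
    if block.n_sites == 0:
        raise ValueError(f"empty block {block.region.name}")
    row = block.subject_ids.index(subject)
    states = block.states[row]
    f = ref_table.freqs[np.arange(block.n_sites), states]
    return float(np.mean(1.0 - f))


def pair_score(
    mt_block: GenotypeBlock,
    nuc_block: GenotypeBlock,
    joint_ref_table: JointReferenceFrequencyTable,
    subject: str,
) -> float:
    """Mean reference rarity of one subject's joint states over all site pairs."""
    if mt_block.n_sites == 0 or nuc_block.n_sites == 0:
        raise ValueError("empty block in pair score")
    if subject not in mt_block.subject_ids or subject not in nuc_block.subject_ids:
        raise ValueError(f"subject {subject!r} missing from a block")
    i = mt_block.subject_ids.index(subject)
    a = mt_block.states[i]  # (m,)
    g = nuc_block.states[nuc_block.subject_ids.index(subject)]  # (k,)
    joint_idx = 3 * a[:, None] + g[None, :]  # code order == JOINT_STATES
    f = np.take_along_axis(
        joint_ref_table.freqs, joint_idx[:, :, None], axis=2
    )[:, :, 0]
    return float(np.mean(1.0 - f))


# ---------------------------------------------------------------------------
# scikit-learn encoders


class FrequencyScoreEncoder(TransformerMixin, BaseEstimator):
    """Per-gene frequency scores from a single-genome state matrix.

    Parameters
    ----------
    group_sizes : list of int
        Number of state columns per gene, in column order.
    feature_names : list of str, optional
        Gene names (defaults to ``g0, g1, ...``).

    ``fit(X)`` takes the reference subjects' state matrix; ``transform(X)``
    returns an (n_subjects, n_genes) score matrix.
    """

    def __init__(self, group_sizes=None, feature_names=None):
        self.group_sizes = group_sizes
        self.feature_names = feature_names

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("reference matrix must be 2-D and nonempty")
        sizes = self.group_sizes if self.group_sizes is not None else [X.shape[1]]
        if sum(sizes) != X.shape[1]:
            raise ValueError("group_sizes do not sum to the column count")
        if min(sizes) < 1:
            raise ValueError("every gene must contribute at least one site")
        n_states = int(X.max()) + 1 if X.size else 2
        self.n_states_ = max(n_states, 2)
        self.state_frequencies_ = np.stack(
            [(X == k).mean(axis=0) for k in range(self.n_states_)], axis=1
        )
        self.group_sizes_ = list(sizes)
        self.feature_names_ = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"g{i}" for i in range(len(sizes))]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "state_frequencies_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count mismatch with fitted reference")
        rarity = 1.0 - np.take_along_axis(
            self.state_frequencies_[None, :, :], X[:, :, None], axis=2
        )[:, :, 0]
        out = np.empty((X.shape[0], len(self.group_sizes_)))
        start = 0
        for j, size in enumerate(self.group_sizes_):
            out[:, j] = rarity[:, start : start + size].mean(axis=1)
            start += size
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)


class PairFrequencyScoreEncoder(TransformerMixin, BaseEstimator):
    """Per-gene-pair joint frequency scores.

    ``X`` is the horizontal concatenation of the mitochondrial state matrix
    (alphabet {0,1}) and the nuclear state matrix (alphabet {0,1,2});
    ``mt_group_sizes`` / ``nuc_group_sizes`` give sites per gene within each
    half. Output columns are mt-major: ``mtGene+nucGene``.

    The transform uses the match-count identity (see module docstring), so
    cost is O(n_subjects x n_reference) per gene pair rather than per site
    pair.
    """

    def __init__(
        self,
        mt_group_sizes=None,
        nuc_group_sizes=None,
        mt_feature_names=None,
        nuc_feature_names=None,
    ):
        self.mt_group_sizes = mt_group_sizes
        self.nuc_group_sizes = nuc_group_sizes
        self.mt_feature_names = mt_feature_names
        self.nuc_feature_names = nuc_feature_names

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("reference matrix must be 2-D and nonempty")
        mt_sizes = list(self.mt_group_sizes or [])
        nuc_sizes = list(self.nuc_group_sizes or [])
        if not mt_sizes or not nuc_sizes:
            raise ValueError("mt_group_sizes and nuc_group_sizes are required")
        if sum(mt_sizes) + sum(nuc_sizes) != X.shape[1]:
            raise ValueError("group sizes do not sum to the column count")
        if min(mt_sizes + nuc_sizes) < 1:
            raise ValueError("every gene must contribute at least one site")
        self.mt_group_sizes_ = mt_sizes
        self.nuc_group_sizes_ = nuc_sizes
        self.n_mt_sites_ = sum(mt_sizes)
        self.reference_states_ = X.copy()
        mt_names = (
            list(self.mt_feature_names)
            if self.mt_feature_names is not None
            else [f"mt{i}" for i in range(len(mt_sizes))]
        )
        nuc_names = (
            list(self.nuc_feature_names)
            if self.nuc_feature_names is not None
            else [f"nuc{i}" for i in range(len(nuc_sizes))]
        )
        self.feature_names_ = [
            f"{m}+{n}" for m in mt_names for n in nuc_names
        ]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_states_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count mismatch with fitted reference")
        ref = self.reference_states_
        n_ref = ref.shape[0]
        n = X.shape[0]

        def match_counts(sizes, offset):
            """Per-gene (n, n_ref) matrices of matching-site counts."""
            out, start = [], offset
            for size in sizes:
                a = X[:, start : start + size]
                b = ref[:, start : start + size]
                m = np.zeros((n, n_ref))
                for k in range(int(max(a.max(initial=0), b.max(initial=0))) + 1):
                    m += (a == k).astype(float) @ (b == k).T.astype(float)
                out.append(m)
                start += size
            return out

        mt_match = match_counts(self.mt_group_sizes_, 0)
        nuc_match = match_counts(self.nuc_group_sizes_, self.n_mt_sites_)
        scores = np.empty((n, len(self.feature_names_)))
        col = 0
        for gi, m_sites in enumerate(self.mt_group_sizes_):
            for hj, k_sites in enumerate(self.nuc_group_sizes_):
                mean_f = (mt_match[gi] * nuc_match[hj]).sum(axis=1) / (
                    n_ref * m_sites * k_sites
                )
                scores[:, col] = 1.0 - mean_f
                col += 1
        return scores

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)


# ---------------------------------------------------------------------------
# block-level feature tables


def _split_blocks(blocks: dict[str, GenotypeBlock]):
    mt = {n: b for n, b in blocks.items() if b.region.is_mitochondrial}
    nuc = {n: b for n, b in blocks.items() if not b.region.is_mitochondrial}
    return mt, nuc


def build_feature_table(
    blocks: dict[str, GenotypeBlock],
    panel: PopulationPanel,
    ref_pop: str,
    mode: str,
) -> pd.DataFrame:
    """Subjects x features frequency-score table.

    ``mode`` selects mitochondrial genes (``mt``), nuclear genes (``nuc``) or
    all mt x nuc gene pairs (``pair``). Every panel subject is scored with the
    reference population's frequency tables, reference subjects included.
    """
    if mode not in ("mt", "nuc", "pair"):
        raise ValueError(f"unknown mode {mode!r}")
    mt, nuc = _split_blocks(blocks)
    use = {"mt": [mt], "nuc": [nuc], "pair": [mt, nuc]}[mode]
    for group in use:
        if not group:
            raise ValueError(f"mode {mode!r} needs blocks of both classes")
        for name, b in group.items():
            if b.n_sites == 0:
                raise ValueError(f"empty block for gene {name}")

    first = next(iter((use[0]).values()))
    subjects = first.subject_ids
    for group in use:
        for b in group.values():
            if b.subject_ids != subjects:
                raise ValueError("blocks disagree on subject ordering")
    ref_rows = _check_ref(first, panel, ref_pop)

    if mode in ("mt", "nuc"):
        group = use[0]
        X = np.column_stack([b.states for b in group.values()])
        enc = FrequencyScoreEncoder(
            group_sizes=[b.n_sites for b in group.values()],
            feature_names=list(group),
        )
    else:
        X = np.column_stack(
            [b.states for b in mt.values()] + [b.states for b in nuc.values()]
        )
        enc = PairFrequencyScoreEncoder(
            mt_group_sizes=[b.n_sites for b in mt.values()],
            nuc_group_sizes=[b.n_sites for b in nuc.values()],
            mt_feature_names=list(mt),
            nuc_feature_names=list(nuc),
        )
    enc.fit(X[ref_rows])
    scores = enc.transform(X)
    return pd.DataFrame(scores, index=pd.Index(subjects, name="subject"),
                        columns=enc.get_feature_names_out())


# ---------------------------------------------------------------------------
# pair-feature-space arithmetic


def pair_feature_space(
    mt_counts: dict[str, int], nuc_counts: dict[str, int]
) -> pd.DataFrame:
    """SNV-pair counts for every (mt gene, nuc gene) combination."""
    rows = [
        {"mt_gene": m, "nuc_gene": n, "n_pairs": cm * cn}
        for m, cm in mt_counts.items()
        for n, cn in nuc_counts.items()
    ]
    return pd.DataFrame(rows)


def load_gene_snv_counts() -> pd.DataFrame:
    """Bundled per-gene SNV counts for the three-population study genes."""
    with resources.files("mitonuclear.data").joinpath(
        "gene_snv_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
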