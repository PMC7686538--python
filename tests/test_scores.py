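import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitonuclear as mn
from mitonuclear.scores import (
    FrequencyScoreEncoder,
    PairFrequencyScoreEncoder,
    joint_reference_frequencies,
    reference_frequencies,
)

from conftest import make_block


def brute_force_pair_scores(mt_states, nuc_states, ref_rows):
    """O(n_mt x n_nuc x N) double-loop oracle for pair scores."""
    n = mt_states.shape[0]
    ref_mt = mt_states[ref_rows]
    ref_nuc = nuc_states[ref_rows]
    n_ref = len(ref_rows)
    out = np.zeros(n)
    for s in range(n):
        total = 0.0
        for i in range(mt_states.shape[1]):
            for j in range(nuc_states.shape[1]):
                f = np.mean(
                    (ref_mt[:, i] == mt_states[s, i])
                    & (ref_nuc[:, j] == nuc_states[s, j])
                )
                total += 1.0 - f
        out[s] = total / (mt_states.shape[1] * nuc_states.shape[1])
    return out


def brute_force_gene_scores(states, ref_rows):
    n, m = states.shape
    out = np.zeros(n)
    for s in range(n):
        total = 0.0
        for j in range(m):
            total += 1.0 - np.mean(states[ref_rows, j] == states[s, j])
        out[s] = total / m
    return out


class TestReferenceFrequencies:
    def test_mt_direct_count(self):
        panel = mn.PopulationPanel(
            {"S0": "REF", "S1": "REF", "S2": "REF", "S3": "REF", "X": "OTH"}
        )
        block = make_block(
            [[0], [0], [1], [1], [0]],
            mitochondrial=True,
            subject_ids=["S0", "S1", "S2", "S3", "X"],
        )
        table = reference_frequencies(block, panel, "REF")
        np.testing.assert_allclose(table.freqs[0], [0.5, 0.5])

    def test_nuc_direct_count(self):
        panel = mn.PopulationPanel(
            {"S0": "REF", "S1": "REF", "S2": "REF", "S3": "REF", "X": "OTH"}
        )
        block = make_block(
            [[0], [1], [1], [2], [0]],
            subject_ids=["S0", "S1", "S2", "S3", "X"],
        )
        table = reference_frequencies(block, panel, "REF")
        np.testing.assert_allclose(table.freqs[0], [0.25, 0.5, 0.25])

    def test_monomorphic_in_reference(self):
        panel = mn.PopulationPanel({"S0": "REF", "S1": "REF", "X": "OTH"})
        block = make_block([[1], [1], [2]], subject_ids=["S0", "S1", "X"])
        table = reference_frequencies(block, panel, "REF")
        np.testing.assert_allclose(table.freqs[0], [0.0, 1.0, 0.0])

    def test_unknown_reference_population(self):
        panel = mn.PopulationPanel({"S0": "A", "S1": "B"})
        block = make_block([[0], [1]], subject_ids=["S0", "S1"])
        with pytest.raises(ValueError, match="absent"):
            reference_frequencies(block, panel, "NOPE")


class TestGeneScore:
    def test_hand_evaluated_example(self):
        # f_ref site1 (0.5, 0.5), site2 (0.75, 0.25); subject carries (1, 1):
        # score = ((1-0.5) + (1-0.25)) / 2 = 0.625
        panel = mn.PopulationPanel(
            {"S0": "REF", "S1": "REF", "S2": "REF", "S3": "REF", "Q": "OTH"}
        )
        states = [[0, 0], [0, 0], [1, 0], [1, 1], [1, 1]]
        block = make_block(
            states, mitochondrial=True, subject_ids=["S0", "S1", "S2", "S3", "Q"]
        )
        table = reference_frequencies(block, panel, "REF")
        assert mn.gene_score(block, table, "Q") == pytest.approx(0.625)

    def test_score_bounds(self):
        panel = mn.PopulationPanel({"S0": "REF", "S1": "REF", "Q": "OTH"})
        block = make_block([[0, 0], [0, 0], [0, 0]],
                           subject_ids=["S0", "S1", "Q"])
        table = reference_frequencies(block, panel, "REF")
        # all carried states fixed in the reference -> 0
        assert mn.gene_score(block, table, "Q") == 0.0
        block2 = make_block([[0, 0], [0, 0], [2, 2]],
                            subject_ids=["S0", "S1", "Q"])
        table2 = reference_frequencies(block2, panel, "REF")
        # all carried states unseen in the reference -> 1
        assert mn.gene_score(block2, table2, "Q") == 1.0


class TestPairScore:
    def test_hand_evaluated_1x1(self):
        # reference joint states (0,hom-ref) 0.25, (0,het) 0.25, (1,hom-alt)
        # 0.5; subject carries (0, hom-ref) -> 1 - 0.25 = 0.75
        panel = mn.PopulationPanel(
            {"S0": "REF", "S1": "REF", "S2": "REF", "S3": "REF", "Q": "OTH"}
        )
        ids = ["S0", "S1", "S2", "S3", "Q"]
        mt = make_block([[0], [0], [1], [1], [0]], mitochondrial=True,
                        subject_ids=ids, name="M")
        nuc = make_block([[0], [1], [2], [2], [0]], subject_ids=ids, name="N")
        table = joint_reference_frequencies(mt, nuc, panel, "REF")
        assert mn.pair_score(mt, nuc, table, "Q") == pytest.approx(0.75)

    def test_unseen_joint_state_contributes_one(self):
        panel = mn.PopulationPanel({"S0": "REF", "S1": "REF", "Q": "OTH"})
        ids = ["S0", "S1", "Q"]
        mt = make_block([[0], [0], [1]], mitochondrial=True,
                        subject_ids=ids, name="M")
        nuc = make_block([[0], [0], [2]], subject_ids=ids, name="N")
        table = joint_reference_frequencies(mt, nuc, panel, "REF")
        assert mn.pair_score(mt, nuc, table, "Q") == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        mt_states = rng.integers(0, 2, (30, 7))
        nuc_states = rng.integers(0, 3, (30, 9))
        ref_rows = np.arange(12)
        ids = [f"S{i}" for i in range(30)]
        panel = mn.PopulationPanel(
            {s: ("REF" if i < 12 else "OTH") for i, s in enumerate(ids)}
        )
        mt = make_block(mt_states, mitochondrial=True, subject_ids=ids, name="M")
        nuc = make_block(nuc_states, subject_ids=ids, name="N")
        table = joint_reference_frequencies(mt, nuc, panel, "REF")
        expected = brute_force_pair_scores(mt_states, nuc_states, ref_rows)
        for i, s in enumerate(ids[:10]):
            assert mn.pair_score(mt, nuc, table, s) == pytest.approx(
                expected[i], abs=1e-12
            )


class TestEncoders:
    def test_pair_encoder_equals_brute_force(self):
        rng = np.random.default_rng(0)
        mt_states = rng.integers(0, 2, (40, 6))
        nuc_states = rng.integers(0, 3, (40, 8))
        ref = np.arange(15)
        enc = PairFrequencyScoreEncoder(
            mt_group_sizes=[2, 4], nuc_group_sizes=[3, 5]
        )
        X = np.column_stack([mt_states, nuc_states])
        enc.fit(X[ref])
        scores = enc.transform(X)
        # compare each gene-pair column against the double loop
        splits_mt = [(0, 2), (2, 6)]
        splits_nuc = [(0, 3), (3, 8)]
        col = 0
        for a, b in splits_mt:
            for c, d in splits_nuc:
                expected = brute_force_pair_scores(
                    mt_states[:, a:b], nuc_states[:, c:d], ref
                )
                np.testing.assert_allclose(
                    scores[:, col], expected, atol=1e-10
                )
                col += 1

    def test_gene_encoder_equals_brute_force(self):
        rng = np.random.default_rng(1)
        states = rng.integers(0, 3, (25, 10))
        ref = np.arange(9)
        enc = FrequencyScoreEncoder(group_sizes=[4, 6]).fit(states[ref])
        scores = enc.transform(states)
        np.testing.assert_allclose(
            scores[:, 0], brute_force_gene_scores(states[:, :4], ref), atol=1e-12
        )
        np.testing.assert_allclose(
            scores[:, 1], brute_force_gene_scores(states[:, 4:], ref), atol=1e-12
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_scores_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n, m, k = rng.integers(4, 15), rng.integers(1, 6), rng.integers(1, 6)
        X = np.column_stack(
            [rng.integers(0, 2, (n, m)), rng.integers(0, 3, (n, k))]
        )
        ref = rng.choice(n, size=rng.integers(2, n), replace=False)
        enc = PairFrequencyScoreEncoder(
            mt_group_sizes=[m], nuc_group_sizes=[k]
        ).fit(X[ref])
        s = enc.transform(X)
        assert (s >= 0).all() and (s <= 1).all()


class TestFeatureTable:
    def test_pair_mode_column_count_is_product(self, small_dataset):
        blocks, panel = small_dataset
        table = mn.build_feature_table(blocks, panel, "GBR", "pair")
        assert table.shape[1] == 2 * 2
        assert list(table.columns) == [
            "MTA+NUCA", "MTA+NUCB", "MTB+NUCA", "MTB+NUCB"
        ]

    def test_modes_and_all_subjects_scored(self, small_dataset):
        blocks, panel = small_dataset
        for mode, ncols in (("mt", 2), ("nuc", 2)):
            table = mn.build_feature_table(blocks, panel, "FIN", mode)
            assert table.shape == (len(panel), ncols)
            assert (table.values >= 0).all() and (table.values <= 1).all()

    def test_reference_subjects_score_population_rarity(self, small_dataset):
        # reference subjects are scored with the same (leave-in) table: their
        # scores sit near the mean reference rarity, not at zero
        blocks, panel = small_dataset
        table = mn.build_feature_table(blocks, panel, "GBR", "mt")
        ref_scores = table.loc[[s for s in table.index if panel[s] == "GBR"]]
        assert ref_scores.values.min() > 0.0

    def test_pair_factorizes_under_independence(self):
        # independent reference mt/nuc states: joint frequency = product, so
        # a pair score equals the bilinear combination of marginal tables
        rng = np.random.default_rng(3)
        n = 4000
        ids = [f"S{i}" for i in range(n)]
        panel = mn.PopulationPanel(
            {s: ("REF" if i < n - 2 else "OTH") for i, s in enumerate(ids)}
        )
        mt = make_block(rng.integers(0, 2, (n, 1)), mitochondrial=True,
                        subject_ids=ids, name="M")
        nuc = make_block(rng.integers(0, 3, (n, 1)), subject_ids=ids, name="N")
        joint = joint_reference_frequencies(mt, nuc, panel, "REF")
        f = reference_frequencies(mt, panel, "REF").freqs[0]
        g = reference_frequencies(nuc, panel, "REF").freqs[0]
        np.testing.assert_allclose(
            joint.freqs[0, 0], np.outer(f, g).ravel(), atol=0.03
        )

    def test_row_permutation_equivariance(self, small_dataset):
        blocks, panel = small_dataset
        table = mn.build_feature_table(blocks, panel, "GBR", "mt")
        ids = list(table.index)
        perm = ids[::-1]
        permuted_blocks = {
            k: b.subset_subjects(perm) for k, b in blocks.items()
        }
        table2 = mn.build_feature_table(permuted_blocks, panel, "GBR", "mt")
        np.testing.assert_allclose(
            table2.values, table.loc[perm].values, atol=1e-12
        )

    def test_empty_block_rejected(self, small_dataset):
        blocks, panel = small_dataset
        broken = dict(blocks)
        b = blocks["MTA"]
        broken["MTA"] = b.subset_sites(np.array([], dtype=int))
        with pytest.raises(ValueError, match="MTA"):
            mn.build_feature_table(broken, panel, "GBR", "mt")


class TestPairFeatureSpace:
    def test_pair_counts_are_products(self):
        df = mn.pair_feature_space({"A": 3, "B": 5}, {"X": 7, "Y": 2})
        assert dict(
            zip(zip(df.mt_gene, df.nuc_gene), df.n_pairs)
        ) == {("A", "X"): 21, ("A", "Y"): 6, ("B", "X"): 35, ("B", "Y"): 10}

    def test_bundled_gene_table_shape(self):
        counts = mn.load_gene_snv_counts()
        assert (counts.genome_class == "mitochondrial").sum() == 13
        assert (counts.genome_class == "nuclear").sum() == 28
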