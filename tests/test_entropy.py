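"""Entropy decomposition and specificity scores against oracles and
closed forms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genespec import (
    EntropySpecificity,
    Partition,
    decompose_entropy,
    score_matrix,
    specificity_scores,
)
from genespec.errors import ValidationError

from ._oracle import oracle_scores
from .conftest import random_partition, random_sparse_gene


def blocks_from_partition(p):
    return [list(np.flatnonzero(p.codes == b)) for b in range(p.r)]


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "x, codes",
        [
            ([2, 2, 4], [0, 0, 1]),
            ([8, 2, 1, 1], [0, 0, 1, 1]),
            ([1, 1, 1, 1], [0, 1, 0, 1]),
            ([5, 3, 2, 2, 7], [0, 1, 2, 0, 1]),
        ],
    )
    def test_matches_brute_force_oracle(self, x, codes):
        r = len(set(codes))
        p = Partition("p", tuple(f"b{i}" for i in range(r)), np.array(codes))
        d = decompose_entropy(x, p)
        s = specificity_scores(d)
        ref = oracle_scores(list(map(float, x)), blocks_from_partition(p))
        assert d.e_t == pytest.approx(ref["e_t"], abs=1e-12)
        assert d.e_b == pytest.approx(ref["e_b"], abs=1e-12)
        assert d.e_w == pytest.approx(ref["e_w"], abs=1e-12)
        assert s.psi == pytest.approx(ref["psi"], abs=1e-12)
        assert s.zeta == pytest.approx(ref["zeta"], abs=1e-12)
        np.testing.assert_allclose(s.psi_blocks, ref["psi_blocks"], atol=1e-12)

    def test_known_values_two_blocks(self):
        # x=[2,2,4] over {c1,c2},{c3}: E_T=1.5 ln2, E_B=ln2, E_W=0.5 ln2,
        # Psi=1/3, psi=[1,0], zeta=1
        p = Partition("p", ("A", "B"), np.array([0, 0, 1]))
        d = decompose_entropy([2, 2, 4], p)
        assert d.e_t == pytest.approx(1.5 * math.log(2), abs=1e-12)
        assert d.e_b == pytest.approx(math.log(2), abs=1e-12)
        assert d.e_w == pytest.approx(0.5 * math.log(2), abs=1e-12)
        s = specificity_scores(d)
        assert s.psi == pytest.approx(1 / 3, abs=1e-12)
        np.testing.assert_allclose(s.psi_blocks, [1.0, 0.0], atol=1e-12)
        assert s.zeta == 1.0

    def test_known_values_skewed(self):
        p = Partition("p", ("A", "B"), np.array([0, 0, 1, 1]))
        d = decompose_entropy([8, 2, 1, 1], p)
        assert d.e_b == pytest.approx(0.45056, abs=1e-5)
        assert d.e_w == pytest.approx(0.53252, abs=1e-5)
        assert d.e_t == pytest.approx(0.98308, abs=1e-5)
        s = specificity_scores(d)
        assert s.psi == pytest.approx(0.5417, abs=1e-4)
        np.testing.assert_allclose(s.psi_blocks, [0.7831, 0.2169], atol=1e-4)
        assert s.zeta == pytest.approx(0.2455, abs=1e-4)

    def test_exhaustive_small_vectors_match_oracle(self):
        # all 3-cell/2-block integer vectors with entries <= 5
        p = Partition("p", ("A", "B"), np.array([0, 0, 1]))
        for x in itertools.product(range(6), repeat=3):
            if sum(1 for v in x if v > 0) < 1 or sum(x) == 0:
                continue
            d = decompose_entropy(x, p)
            s = specificity_scores(d)
            ref = oracle_scores(list(map(float, x)), [[0, 1], [2]])
            assert d.e_t == pytest.approx(ref["e_t"], abs=1e-12)
            if ref["psi"] is None:
                assert s.degenerate_flag == "zero_total"
            else:
                assert s.psi == pytest.approx(ref["psi"], abs=1e-12)
                assert s.zeta == pytest.approx(ref["zeta"], abs=1e-12)
                np.testing.assert_allclose(
                    s.psi_blocks, ref["psi_blocks"], atol=1e-12
                )


class TestClosedForms:
    def test_uniform_gene_equal_blocks(self):
        # uniform x over r equal blocks of m cells: Psi = ln m / ln(rm),
        # zeta = 0, psi uniform
        for r, m in [(2, 2), (2, 5), (4, 3), (5, 8)]:
            codes = np.repeat(np.arange(r), m)
            p = Partition("p", tuple(f"b{i}" for i in range(r)), codes)
            s = specificity_scores(decompose_entropy(np.ones(r * m), p))
            if m > 1:
                assert s.psi == pytest.approx(
                    math.log(m) / math.log(r * m), abs=1e-12
                )
            assert abs(s.zeta) <= 1e-12
            np.testing.assert_allclose(s.psi_blocks, np.full(r, 1 / r), atol=1e-12)

    def test_block_exclusive_gene(self):
        codes = np.repeat([0, 1, 2], 4)
        p = Partition("p", ("a", "b", "c"), codes)
        x = np.zeros(12)
        x[4:8] = [3, 1, 4, 1]
        s = specificity_scores(decompose_entropy(x, p))
        assert s.psi == 1.0
        assert s.zeta == 1.0
        np.testing.assert_allclose(s.psi_blocks, [0, 1, 0], atol=0)


class TestDegeneracies:
    def test_zero_total_is_error_in_decompose(self, two_block_partition):
        with pytest.raises(ValidationError):
            decompose_entropy([0, 0, 0, 0], two_block_partition)

    def test_negative_is_error(self, two_block_partition):
        with pytest.raises(ValidationError):
            decompose_entropy([1, -1, 2, 0], two_block_partition)

    def test_single_expressing_cell_flags_zero_total(self, two_block_partition):
        d = decompose_entropy([0, 3, 0, 0], two_block_partition)
        s = specificity_scores(d)
        assert s.degenerate_flag == "zero_total"
        assert np.isnan(s.psi) and np.isnan(s.zeta)

    def test_one_cell_per_block_flags_zero_within(self, two_block_partition):
        # E_T > 0 but every block has one expressing cell: Psi=0,
        # psi_blocks = block mass fractions, zeta from that composition
        d = decompose_entropy([3, 0, 0, 1], two_block_partition)
        s = specificity_scores(d)
        assert s.degenerate_flag == "zero_within"
        assert s.psi == 0.0
        np.testing.assert_allclose(s.psi_blocks, [0.75, 0.25], atol=1e-12)
        ref = oracle_scores([3, 0, 0, 1], [[0, 1], [2, 3]])
        assert s.zeta == pytest.approx(ref["zeta"], abs=1e-12)


class TestInvariants:
    def test_conservation_and_normalization_random(self, rng):
        for _ in range(200):
            r = int(rng.integers(2, 8))
            n = int(rng.integers(r * 2, 60))
            p = random_partition(rng, n, r)
            x = random_sparse_gene(rng, n)
            d = decompose_entropy(x, p)
            assert abs(d.e_t - (d.e_b + d.e_w)) <= 1e-10 * max(d.e_t, 1.0)
            assert np.isclose(d.p_block.sum(), 1.0, atol=1e-12)
            s = specificity_scores(d)
            if s.degenerate_flag == "none":
                assert abs(s.psi_blocks.sum() - 1.0) <= 1e-10
            assert 0 <= s.psi <= 1 and 0 <= s.zeta <= 1
            assert ((s.psi_blocks >= 0) & (s.psi_blocks <= 1)).all()
            assert -1e-12 <= d.e_b <= math.log(p.r) + 1e-12
            for e_c, size in zip(d.e_block, p.block_sizes()):
                assert -1e-12 <= e_c <= math.log(size) + 1e-12

    def test_label_order_invariance_bitwise(self, rng):
        for _ in range(25):
            r = int(rng.integers(2, 7))
            n = int(rng.integers(r * 2, 40))
            p = random_partition(rng, n, r)
            x = random_sparse_gene(rng, n)
            s = specificity_scores(decompose_entropy(x, p))
            order = list(p.block_labels)
            rng.shuffle(order)
            p2 = p.reorder(order)
            s2 = specificity_scores(decompose_entropy(x, p2))
            assert s.psi == s2.psi  # bit-identical
            assert s.zeta == s2.zeta
            for lab in p.block_labels:
                i = p.block_labels.index(lab)
                j = p2.block_labels.index(lab)
                assert s.psi_blocks[i] == s2.psi_blocks[j]

    def test_scale_invariance(self, rng):
        for scale in [0.001, 3.0, 1e6]:
            p = random_partition(rng, 30, 4)
            x = random_sparse_gene(rng, 30)
            s1 = specificity_scores(decompose_entropy(x, p))
            s2 = specificity_scores(decompose_entropy(x * scale, p))
            assert s1.psi == pytest.approx(s2.psi, abs=1e-12)
            assert s1.zeta == pytest.approx(s2.zeta, abs=1e-12)
            np.testing.assert_allclose(s1.psi_blocks, s2.psi_blocks, atol=1e-12)

    def test_log_base_invariance(self, rng):
        # entropies computed in base 2 scale by 1/ln2; the three metrics are
        # ratios, so rebuilding them from scaled terms changes nothing
        p = random_partition(rng, 40, 5)
        x = random_sparse_gene(rng, 40)
        d = decompose_entropy(x, p)
        s = specificity_scores(d)
        k = 1.0 / math.log(2)
        psi2 = (d.e_w * k) / (d.e_t * k)
        comp2 = d.p_block * d.e_block * k / (d.e_w * k)
        h2 = -sum(c * math.log(c, 2) for c in comp2 if c > 0)
        zeta2 = 1 - h2 / math.log2(p.r)
        assert s.psi == pytest.approx(psi2, abs=1e-12)
        assert s.zeta == pytest.approx(zeta2, abs=1e-12)

    def test_hierarchical_additivity(self, rng):
        # E_B(fine) = E_B(coarse) + sum_C p_C E_B(fine within C)
        for _ in range(30):
            n = int(rng.integers(12, 50))
            coarse = random_partition(rng, n, int(rng.integers(2, 4)))
            # refine each coarse block independently
            fine_codes = np.zeros(n, dtype=int)
            next_code = 0
            for b in range(coarse.r):
                cells = np.flatnonzero(coarse.codes == b)
                k = int(rng.integers(1, 4))
                sub = rng.integers(0, k, cells.size)
                for s_ in np.unique(sub):
                    fine_codes[cells[sub == s_]] = next_code
                    next_code += 1
            fine = Partition(
                "fine", tuple(f"f{i}" for i in range(next_code)), fine_codes
            )
            x = random_sparse_gene(rng, n)
            d_f = decompose_entropy(x, fine)
            d_c = decompose_entropy(x, coarse)
            within = 0.0
            for b in range(coarse.r):
                cells = np.flatnonzero(coarse.codes == b)
                if x[cells].sum() == 0:
                    continue
                sub_fine = fine_codes[cells]
                if len(np.unique(sub_fine)) < 2:
                    continue  # E_B of a one-block restriction is 0
                labels, codes = np.unique(sub_fine, return_inverse=True)
                sub_p = Partition(
                    "s", tuple(map(str, labels)), codes.astype(np.intp)
                )
                within += d_c.p_block[b] * decompose_entropy(x[cells], sub_p).e_b
            assert d_f.e_b == pytest.approx(d_c.e_b + within, abs=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 30), min_size=4, max_size=12),
        seed=st.integers(0, 10_000),
    )
    def test_property_conservation_random(self, x, seed):
        x = np.array(x, dtype=float)
        if (x > 0).sum() < 1 or x.sum() == 0:
            return
        rng = np.random.default_rng(seed)
        p = random_partition(rng, x.size, 2)
        d = decompose_entropy(x, p)
        assert abs(d.e_t - (d.e_b + d.e_w)) <= 1e-10 * max(d.e_t, 1.0)
        # grouping identity: E_B equals the direct form -sum p_C log p_C
        direct = -sum(pc * math.log(pc) for pc in d.p_block if pc > 0)
        assert d.e_b == pytest.approx(direct, abs=1e-10)


class TestScoreMatrix:
    def test_matches_per_gene_calls(self, rng):
        n, G, r = 40, 15, 3
        X = np.array(
            [random_sparse_gene(rng, n) for _ in range(G)]
        ).T
        p = random_partition(rng, n, r)
        tab = score_matrix(X, p)
        for g in range(G):
            s = specificity_scores(decompose_entropy(X[:, g], p))
            assert tab["Psi"].iloc[g] == pytest.approx(s.psi, abs=1e-14, nan_ok=True)
            assert tab["zeta"].iloc[g] == pytest.approx(s.zeta, abs=1e-14, nan_ok=True)

    def test_zero_gene_flagged(self, two_block_partition):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        tab = score_matrix(X, two_block_partition)
        assert tab["degenerate_flag"].tolist() == ["none", "zero_total"]
        assert np.isnan(tab["Psi"].iloc[1])

    def test_chunking_does_not_change_results(self, rng):
        n, G = 30, 17
        X = np.array([random_sparse_gene(rng, n) for _ in range(G)]).T
        p = random_partition(rng, n, 4)
        base = EntropySpecificity().fit(X, p)
        for chunk in (1, 3, 5, 16, 100):
            est = EntropySpecificity(chunk_size=chunk).fit(X, p)
            np.testing.assert_array_equal(est.psi_, base.psi_)
            np.testing.assert_array_equal(est.zeta_, base.zeta_)
            np.testing.assert_array_equal(est.psi_blocks_, base.psi_blocks_)

    def test_gene_order_permutation_permutes_rows(self, rng):
        n, G = 25, 8
        X = np.array([random_sparse_gene(rng, n) for _ in range(G)]).T
        p = random_partition(rng, n, 3)
        perm = rng.permutation(G)
        t1 = score_matrix(X, p)
        t2 = score_matrix(X[:, perm], p)
        np.testing.assert_array_equal(
            t1["Psi"].to_numpy()[perm], t2["Psi"].to_numpy()
        )
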