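"""Kimura-2P distance, LTR dating, synteny chaining, divergence histogram."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorkit.compgen import (
    SaturationError,
    SyntenyAnchor,
    call_synteny_blocks,
    divergence_histogram,
    kimura2p,
    ltr_insertion_time,
)
from anchorkit.synthetic import simulate_divergent_pair

# Hand evaluation of -1/2 ln((1-2P-Q) sqrt(1-2Q)) at P=0.10, Q=0.05:
# (0.75 * sqrt(0.90)) = 0.7115124735..., K = 0.1701811651403471
K_P10_Q05 = 0.1701811651403471


def _pair_with(P_count, Q_count, n=100):
    """Aligned pair with exactly the given transition/transversion counts."""
    a = ("ACGT" * ((n + 3) // 4))[:n]
    b = list(a)
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv = {"A": "C", "G": "T", "C": "A", "T": "G"}
    for i in range(P_count):
        b[i] = ts[b[i]]
    for i in range(P_count, P_count + Q_count):
        b[i] = tv[b[i]]
    return a, "".join(b)


class TestKimura2P:
    def test_identical_sequences_zero_distance(self):
        r = kimura2p("ACGT" * 25, "ACGT" * 25)
        assert (r.P, r.Q, r.K) == (0.0, 0.0, 0.0)
        assert r.n_sites == 100

    def test_hand_evaluated_closed_form(self):
        a, b = _pair_with(10, 5, 100)
        r = kimura2p(a, b)
        assert r.P == pytest.approx(0.10) and r.Q == pytest.approx(0.05)
        assert r.K == pytest.approx(K_P10_Q05, abs=1e-9)

    def test_gaps_and_ambiguity_excluded_from_sites(self):
        r = kimura2p("ACGTN-", "ACGTAC")
        assert r.n_sites == 4 and r.K == 0.0

    def test_saturation_raises(self):
        a, b = _pair_with(50, 0, 100)  # P = 0.5, Q = 0
        with pytest.raises(SaturationError):
            kimura2p(a, b)

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValueError):
            kimura2p("NNN", "ACG")

    def test_symmetry_and_monotonicity_in_transitions(self):
        for p_count in range(0, 30, 3):
            a, b = _pair_with(p_count, 5, 100)
            assert kimura2p(a, b).K == kimura2p(b, a).K
        ks = [kimura2p(*_pair_with(p, 5, 100)).K for p in range(0, 40, 5)]
        assert all(k2 > k1 for k1, k2 in zip(ks, ks[1:]))

    def test_small_divergence_first_order_expansion(self):
        # K ~ P + Q within 5% whenever P + Q <= 0.05
        for p_count, q_count in [(1, 0), (0, 1), (2, 1), (3, 2), (4, 1)]:
            r = kimura2p(*_pair_with(p_count, q_count, 100))
            assert r.K == pytest.approx(r.P + r.Q, rel=0.05)

    def test_simulated_pair_recovers_injected_proportions(self):
        a, b = simulate_divergent_pair(20_000, 0.10, 0.05, seed=7)
        r = kimura2p(a, b)
        assert r.P == pytest.approx(0.10, abs=0.01)
        assert r.Q == pytest.approx(0.05, abs=0.01)


class TestLtrInsertionTime:
    def test_direct_arithmetic(self):
        assert ltr_insertion_time(0.26, 1.3e-8) == pytest.approx(1.0e7)
        assert ltr_insertion_time(0.0) == 0.0

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            ltr_insertion_time(0.1, 0.0)
        with pytest.raises(ValueError):
            ltr_insertion_time(0.1, -1e-8)


def _collinear(n, chrom=("A1", "B1"), start_a=0, start_b=0, inverted=False):
    out = []
    for k in range(n):
        ib = start_b + (n - 1 - k if inverted else k)
        out.append(
            SyntenyAnchor(
                gene_a=f"a{start_a + k}", index_a=start_a + k,
                gene_b=f"b{ib}", index_b=ib,
                chrom_a=chrom[0], chrom_b=chrom[1],
            )
        )
    return out


def _longest_chain_oracle(anchors, sign, max_gap):
    """Quadratic DP over anchors sorted by rank on genome A (independent of
    the implementation's chain extraction)."""
    srt = sorted(anchors, key=lambda a: (a.index_a, a.index_b))
    n = len(srt)
    best = 0
    dp = [1] * n
    for i in range(n):
        for j in range(i):
            da = srt[i].index_a - srt[j].index_a
            db = (srt[i].index_b - srt[j].index_b) * sign
            if 0 < da <= max_gap and 0 < db <= max_gap:
                dp[i] = max(dp[i], dp[j] + 1)
        best = max(best, dp[i])
    return best


class TestSyntenyBlocks:
    def test_thirty_collinear_pairs_one_forward_block(self):
        blocks = call_synteny_blocks(_collinear(30))
        assert len(blocks) == 1
        assert blocks[0].direction == "forward" and blocks[0].n_pairs == 30

    def test_twentynine_pairs_below_threshold(self):
        assert call_synteny_blocks(_collinear(29)) == []

    def test_inverted_block_detected(self):
        blocks = call_synteny_blocks(_collinear(35, inverted=True))
        assert len(blocks) == 1
        assert blocks[0].direction == "inverted" and blocks[0].n_pairs == 35

    def test_duplicate_anchors_deduplicated(self):
        anchors = _collinear(30)
        blocks = call_synteny_blocks(anchors + anchors[:5])
        assert len(blocks) == 1 and blocks[0].n_pairs == 30

    def test_blocks_respect_chromosome_pairs(self):
        a = _collinear(30, chrom=("A1", "B1"))
        b = _collinear(30, chrom=("A2", "B2"), start_a=100, start_b=100)
        blocks = call_synteny_blocks(a + b)
        assert sorted((bl.chrom_a, bl.chrom_b) for bl in blocks) == [("A1", "B1"), ("A2", "B2")]

    def test_rank_gap_limit_breaks_chains(self):
        left = _collinear(20)
        right = _collinear(20, start_a=40, start_b=40)  # gap 20 > max_rank_gap
        blocks = call_synteny_blocks(left + right, min_pairs=10)
        assert [b.n_pairs for b in blocks] == [20, 20]

    def test_matches_dynamic_programming_oracle_on_random_instances(self):
        rng = random.Random(20_250_901)
        for _ in range(200):
            n = rng.randint(5, 40)
            anchors = [
                SyntenyAnchor(
                    gene_a=f"a{i}", index_a=rng.randint(0, 25),
                    gene_b=f"b{i}", index_b=rng.randint(0, 25),
                    chrom_a="A1", chrom_b="B1",
                )
                for i in range(n)
            ]
            # anchors must be unique gene pairs and strictly ordered per gene
            blocks = call_synteny_blocks(anchors, min_pairs=2, max_rank_gap=5)
            oracle = max(
                _longest_chain_oracle(anchors, +1, 5),
                _longest_chain_oracle(anchors, -1, 5),
            )
            if oracle >= 2:
                assert max(b.n_pairs for b in blocks) == oracle
            else:
                assert blocks == []


class TestDivergenceHistogram:
    def test_hand_binned_example(self):
        h = divergence_histogram([0.149, 0.151, 0.31], bin_width=0.01)
        occupied = {(round(b.lo, 2), round(b.hi, 2)): b.count for b in h.bins if b.count}
        assert occupied == {(0.14, 0.15): 1, (0.15, 0.16): 1, (0.31, 0.32): 1}
        assert h.modal_bin == pytest.approx((0.14, 0.15))  # tie -> smaller bin

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            divergence_histogram([])

    def test_all_equal_values_single_bin(self):
        h = divergence_histogram([0.2, 0.2, 0.2], bin_width=0.01)
        assert sum(b.count > 0 for b in h.bins) == 1
        assert h.modal_bin[0] == pytest.approx(0.2)

    def test_simulated_divergence_peak_recovered(self):
        # pairs mutated at ~0.15 substitutions/site produce a modal bin there
        rng = np.random.default_rng(3)
        ks = []
        for i in range(120):
            a, b = simulate_divergent_pair(2_000, 0.10, 0.04, seed=int(rng.integers(2**31)))
            ks.append(kimura2p(a, b).K)
        h = divergence_histogram(ks, bin_width=0.01)
        assert 0.12 <= h.modal_bin[0] <= 0.18
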