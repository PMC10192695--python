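"""Ordinal symbolization, STE estimator oracles, network thresholding."""

import itertools
import math

import numpy as np
import pytest

from ictalnet.signal_io import EEGSegment
from ictalnet.stenet import (STEConfig, SymbolSequence, ste_matrix, symbolize,
                             symbolic_transfer_entropy, threshold_network,
                             STEMatrix)
from ictalnet.synthdata import generate_coupled_pair


def brute_force_symbol(window):
    """Rank of the stable argsort permutation among all m! permutations."""
    m = len(window)
    perm = tuple(np.argsort(window, kind="stable"))
    return sorted(itertools.permutations(range(m))).index(perm)


def brute_force_ste(sj, si, n_symbols):
    """Direct histogram STE with k=l=1 from explicit dictionaries."""
    from collections import Counter
    triples = Counter()
    for n in range(len(si) - 1):
        triples[(si[n + 1], si[n], sj[n])] += 1
    pairs_ij = Counter()
    pairs_fi = Counter()
    singles = Counter()
    for (f, i, j), c in triples.items():
        pairs_ij[(i, j)] += c
        pairs_fi[(f, i)] += c
        singles[i] += c
    total = sum(triples.values())
    te = 0.0
    for (f, i, j), c in triples.items():
        p = c / total
        cond_joint = c / pairs_ij[(i, j)]
        cond_marg = pairs_fi[(f, i)] / singles[i]
        te += p * math.log2(cond_joint / cond_marg)
    return max(te, 0.0)


class TestSymbolize:
    def test_monotone_series_single_pattern(self):
        s = symbolize(np.array([1.0, 2, 3, 4, 5]), STEConfig())
        assert len(s) == 3
        assert len(set(s.symbols.tolist())) == 1
        assert s.symbols[0] == 0  # ascending pattern is lexicographically first

    def test_constant_series_single_pattern_by_tie_rule(self):
        s = symbolize(np.zeros(10), STEConfig())
        assert len(set(s.symbols.tolist())) == 1
        assert s.symbols[0] == 0

    def test_single_windows_match_brute_force(self):
        cfg = STEConfig()
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = rng.standard_normal(3)
            got = symbolize(w, cfg).symbols[0]
            assert got == brute_force_symbol(w)
        # the specific descending-start case (3,1,2)
        assert symbolize(np.array([3.0, 1.0, 2.0]), cfg).symbols[0] \
            == brute_force_symbol([3.0, 1.0, 2.0])

    def test_all_six_patterns_reachable(self):
        cfg = STEConfig()
        seen = set()
        for perm in itertools.permutations([1.0, 2.0, 3.0]):
            seen.add(int(symbolize(np.array(perm), cfg).symbols[0]))
        assert seen == set(range(6))

    def test_length_contract(self):
        s = symbolize(np.arange(100.0), STEConfig(embed_m=4, delay_tau=3))
        assert len(s) == 100 - 3 * 3
        with pytest.raises(ValueError):
            symbolize(np.arange(5.0), STEConfig(embed_m=3, delay_tau=4))

    def test_tau_spacing(self):
        # with tau=2 the window takes every other sample
        x = np.array([0.0, 100.0, 1.0, -100.0, 2.0])
        s = symbolize(x, STEConfig(embed_m=3, delay_tau=2))
        assert len(s) == 1
        assert s.symbols[0] == 0  # (0, 1, 2) ascending


class TestSTEEstimator:
    def test_identical_streams_give_exact_zero(self):
        cfg = STEConfig()
        rng = np.random.default_rng(1)
        s = symbolize(rng.standard_normal(3000), cfg)
        assert symbolic_transfer_entropy(s, s, cfg) == 0.0

    def test_matches_hand_enumeration_on_short_streams(self):
        """Oracle equivalence on m=2 symbol streams of length <= 30."""
        cfg = STEConfig(embed_m=2)
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = rng.integers(8, 31)
            si = rng.integers(0, 2, n)
            sj = rng.integers(0, 2, n)
            a = SymbolSequence(si, n + 1, cfg)
            b = SymbolSequence(sj, n + 1, cfg)
            got = symbolic_transfer_entropy(b, a, cfg)
            want = brute_force_ste(sj.tolist(), si.tolist(), 2)
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_hand_enumeration_m3(self):
        cfg = STEConfig(embed_m=3)
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(10, 31)
            si = rng.integers(0, 6, n)
            sj = rng.integers(0, 6, n)
            got = symbolic_transfer_entropy(
                SymbolSequence(sj, n, cfg), SymbolSequence(si, n, cfg), cfg)
            want = brute_force_ste(sj.tolist(), si.tolist(), 6)
            assert got == pytest.approx(want, abs=1e-12)

    def test_nonnegative_and_floor(self):
        cfg = STEConfig()
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = SymbolSequence(rng.integers(0, 6, 200), 200, cfg)
            b = SymbolSequence(rng.integers(0, 6, 200), 200, cfg)
            assert symbolic_transfer_entropy(a, b, cfg) >= 0.0

    def test_independent_streams_small_bias(self):
        """Plug-in bias on independent uniform symbols vanishes with n."""
        cfg = STEConfig()
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = SymbolSequence(rng.integers(0, 6, 100_000), 100_000, cfg)
            b = SymbolSequence(rng.integers(0, 6, 100_000), 100_000, cfg)
            vals.append(symbolic_transfer_entropy(b, a, cfg))
        assert max(vals) < 0.01

    def test_direction_recovery_on_coupled_pair(self):
        cfg = STEConfig()
        x, y = generate_coupled_pair(10_000, 0.8, seed=0)
        sx, sy = symbolize(x, cfg), symbolize(y, cfg)
        assert symbolic_transfer_entropy(sx, sy, cfg) \
            > symbolic_transfer_entropy(sy, sx, cfg)

    def test_length_mismatch_rejected(self):
        cfg = STEConfig()
        a = SymbolSequence(np.zeros(10, dtype=int), 12, cfg)
        b = SymbolSequence(np.zeros(11, dtype=int), 13, cfg)
        with pytest.raises(ValueError):
            symbolic_transfer_entropy(a, b, cfg)

    def test_higher_order_histories_run(self):
        cfg = STEConfig(history_k=2, history_l=2)
        rng = np.random.default_rng(5)
        a = symbolize(rng.standard_normal(2000), cfg)
        b = symbolize(rng.standard_normal(2000), cfg)
        v = symbolic_transfer_entropy(a, b, cfg)
        assert np.isfinite(v) and v >= 0


class TestSTEMatrix:
    def test_diagonal_zero_and_shape(self, ictal_segment):
        seg, _ = ictal_segment
        m = ste_matrix(seg)
        assert m.values.shape == (23, 23)
        assert np.all(np.diag(m.values) == 0)
        assert np.all(np.isfinite(m.values))

    def test_independent_channels_sit_at_bias_floor(self):
        """Independent noise channels stay below 0.04 bits everywhere.

        The plug-in estimator carries a small-sample bias of roughly
        0.02-0.03 bits at n=2558 with 6 symbols; this pins the empirical
        noise floor that motivates the 0.02 edge threshold.
        """
        rng = np.random.default_rng(6)
        seg = EEGSegment(data=rng.standard_normal((23, 2560)), rate=256)
        m = ste_matrix(seg)
        off = m.values[~np.eye(23, dtype=bool)]
        assert off.max() < 0.04
        assert 0.005 < off.mean() < 0.03

    def test_focus_block_mean_exceeds_background(self, ictal_segment):
        seg, gt = ictal_segment
        m = ste_matrix(seg)
        block = np.zeros((23, 23), dtype=bool)
        block[np.ix_(range(6), range(6))] = True
        np.fill_diagonal(block, False)
        background = ~block & ~np.eye(23, dtype=bool)
        assert m.values[block].mean() > m.values[background].mean()

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((23, 1000))
        m = ste_matrix(EEGSegment(data=data), STEConfig())
        perm = rng.permutation(23)
        m_perm = ste_matrix(EEGSegment(data=data[perm]), STEConfig())
        np.testing.assert_allclose(m_perm.values, m.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_wrong_channel_count_refused(self):
        seg = EEGSegment(data=np.random.default_rng(0).standard_normal((5, 1000)))
        with pytest.raises(ValueError):
            ste_matrix(seg)
        m = ste_matrix(seg, override_channels=True)
        assert m.values.shape == (5, 5)


class TestThresholdNetwork:
    def _matrix(self, values):
        n = values.shape[0]
        return STEMatrix(values=values, channel_names=[f"c{i}" for i in range(n)])

    def test_hand_counted_edges(self):
        v = np.array([[0, .05, .01], [.03, 0, .09], [0, 0, 0]])
        net = threshold_network(self._matrix(v), 0.02)
        assert net.n_edges == 3
        assert set(net.graph.edges) == {("c0", "c1"), ("c1", "c0"), ("c1", "c2")}

    def test_all_below_threshold_empty(self):
        net = threshold_network(self._matrix(np.full((4, 4), 0.001)), 0.02)
        assert net.n_edges == 0
        assert net.graph.number_of_nodes() == 4

    def test_sparser_threshold_is_subset(self, ictal_segment):
        seg, _ = ictal_segment
        m = ste_matrix(seg)
        loose = set(threshold_network(m, 0.02).graph.edges)
        tight = set(threshold_network(m, 0.08).graph.edges)
        assert tight <= loose

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_network(self._matrix(np.zeros((3, 3))), -0.1)

    def test_edge_weights_carry_ste_values(self):
        v = np.zeros((3, 3))
        v[0, 1] = 0.5
        net = threshold_network(self._matrix(v), 0.02)
        assert net.graph["c0"]["c1"]["weight"] == 0.5
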