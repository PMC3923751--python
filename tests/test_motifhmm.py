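import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_motif_hmm
from oracles import (brute_force_begin_end, brute_force_loglik,
                     brute_force_viterbi)

from dismotif.motifhmm import (MotifHMM, NullModel, Batch, _Compiled, _backward,
                               _forward, build_hmm, expected_counts, forward_batch,
                               log_likelihood, match_positions,
                               mean_length_to_ext, null_log_likelihood,
                               posterior_begin_end, posterior_states, viterbi)

# reduced alphabet used for exhaustive-enumeration checks
REDUCED = "ACD"


def seq_strategy(min_len, max_len):
    return st.text(alphabet=REDUCED, min_size=min_len, max_size=max_len)


class TestBuild:
    @pytest.mark.parametrize("W", [1, 2, 4])
    def test_valid_model_of_requested_width(self, W):
        h = build_hmm(W, np.full(20, 0.05), np.random.default_rng(0))
        assert h.W == W and h.states.count("Cflank") == 1
        assert sum(s.startswith("M") for s in h.states) == W
        h.validate()

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            build_hmm(0, np.full(20, 0.05), np.random.default_rng(0))

    def test_fixed_seed_reproducible(self):
        a = build_hmm(4, np.full(20, 0.05), np.random.default_rng(7))
        b = build_hmm(4, np.full(20, 0.05), np.random.default_rng(7))
        assert np.array_equal(a.match_emis, b.match_emis)

    def test_json_round_trip(self, tmp_path):
        h = build_hmm(3, np.full(20, 0.05), np.random.default_rng(1))
        h.to_json(tmp_path / "h.json")
        h2 = MotifHMM.from_json(tmp_path / "h.json")
        assert np.allclose(h2.trans, h.trans) and np.allclose(h2.match_emis, h.match_emis)


class TestAgainstEnumeration:
    """Forward, Viterbi and posteriors must agree with exhaustive
    path enumeration on every short sequence over a reduced alphabet."""

    @pytest.mark.parametrize("W", [1, 2])
    def test_all_sequences_up_to_length_6(self, W):
        rng = np.random.default_rng(10 + W)
        h = random_motif_hmm(W, rng)
        for L in range(max(W, 1), 6):
            for tup in itertools.product(REDUCED, repeat=L):
                seq = "".join(tup)
                assert log_likelihood(h, seq) == pytest.approx(
                    brute_force_loglik(h, seq), abs=1e-9)

    def test_viterbi_matches_enumeration(self):
        rng = np.random.default_rng(3)
        h = random_motif_hmm(2, rng)
        for seq in ["ACDAC", "AAAA", "CCDD", "DACADA"]:
            path, lp = viterbi(h, seq)
            bpath, blp = brute_force_viterbi(h, seq)
            assert lp == pytest.approx(blp, abs=1e-9)
            assert tuple(path) == bpath

    def test_begin_end_posteriors_match_enumeration(self):
        rng = np.random.default_rng(4)
        h = random_motif_hmm(2, rng)
        for seq in ["ACDAC", "DDCA", "ACACAC"]:
            begin, end = posterior_begin_end(h, seq)
            bb, be = brute_force_begin_end(h, seq)
            np.testing.assert_allclose(begin, bb, atol=1e-9)
            np.testing.assert_allclose(end, be, atol=1e-9)


class TestProperties:
    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 3), seq_strategy(3, 12), st.integers(0, 10 ** 6))
    def test_forward_backward_agree(self, W, seq, seed):
        h = random_motif_hmm(W, np.random.default_rng(seed))
        if len(seq) < W:
            return
        c = _Compiled(h)
        b = Batch([seq])
        ll, _ = _forward(c, b)
        beta = _backward(c, b)
        x0 = c.log_emis[:, b.X[0, 0]]
        ll_b = np.logaddexp.reduce(c.log_init + x0 + beta[0, 0])
        assert ll_b == pytest.approx(ll[0], abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 3), seq_strategy(3, 10), st.integers(0, 10 ** 6))
    def test_viterbi_bounded_by_forward_and_oops_passage(self, W, seq, seed):
        h = random_motif_hmm(W, np.random.default_rng(seed))
        if len(seq) < W:
            return
        path, lp = viterbi(h, seq)
        assert lp <= log_likelihood(h, seq) + 1e-12
        assert len(match_positions(h, path)) == W  # exactly one motif passage

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 3), seq_strategy(3, 10), st.integers(0, 10 ** 6))
    def test_posterior_normalization(self, W, seq, seed):
        h = random_motif_hmm(W, np.random.default_rng(seed))
        if len(seq) < W:
            return
        begin, end = posterior_begin_end(h, seq)
        assert begin.sum() == pytest.approx(1.0, abs=1e-6)
        assert end.sum() == pytest.approx(1.0, abs=1e-6)
        post = posterior_states(h, seq)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_match_on_homopolymer_gives_flat_begin(self):
        """With match emissions equal to a uniform background and a
        homopolymer sequence, no begin position is preferred over another
        except through the (symmetric) flank-length profile."""
        h = build_hmm(2, np.full(20, 0.05), np.random.default_rng(0), mean_length=6.0)
        h.match_emis = np.full((2, 20), 0.05)
        # suppress inserts: with inserts allowed, early begin positions
        # leave more room for insertions and are genuinely preferred
        h.trans[1, 2], h.trans[1, 3] = 1.0, 0.0
        begin, _ = posterior_begin_end(h, "AAAAAA")
        feasible = begin[:-1]  # last begin position cannot fit W=2
        assert np.allclose(feasible, feasible[0], atol=1e-12)


class TestBatchConsistency:
    def test_batch_equals_single_sequence_forward(self):
        h = random_motif_hmm(2, np.random.default_rng(5))
        seqs = ["ACDACDA", "CCC", "DADD", "ACACACACAC"]
        ll = forward_batch(h, seqs)
        for s, l in zip(seqs, ll):
            assert log_likelihood(h, s) == pytest.approx(float(l), abs=1e-12)

    def test_short_sequence_rejected(self):
        h = random_motif_hmm(3, np.random.default_rng(6))
        with pytest.raises(ValueError):
            log_likelihood(h, "AC")

    def test_expected_counts_total_matches_gamma_mass(self):
        h = random_motif_hmm(2, np.random.default_rng(8))
        seqs = ["ACDAD", "CADC"]
        stats = expected_counts(h, seqs)
        # one initial state per sequence; one termination per sequence
        assert stats.init.sum() == pytest.approx(len(seqs), abs=1e-9)
        assert stats.trans[:, h.K].sum() == pytest.approx(len(seqs), abs=1e-9)
        # match emissions: one visit to each match state per sequence (OOPS)
        assert stats.emis.sum() == pytest.approx(len(seqs) * h.W, abs=1e-9)


class TestNullModel:
    def test_closed_form(self):
        n = NullModel(np.full(20, 0.05), 0.9)
        seq = "ACDE"
        expected = 4 * np.log(0.05) + 4 * np.log(0.9) + np.log(0.1)
        assert null_log_likelihood(n, seq) == pytest.approx(expected, abs=1e-12)

    def test_per_residue_summation_oracle(self):
        rng = np.random.default_rng(9)
        bg = rng.dirichlet(np.ones(20))
        n = NullModel(bg, 0.95)
        seq = "MNPQRSTVWY"
        direct = sum(np.log(bg["ACDEFGHIKLMNPQRSTVWY".index(ch)]) for ch in seq)
        direct += len(seq) * np.log(0.95) + np.log(0.05)
        assert null_log_likelihood(n, seq) == pytest.approx(direct, abs=1e-12)

    def test_empty_sequence_guard(self):
        n = NullModel(np.full(20, 0.05), 0.9)
        with pytest.raises(ValueError):
            null_log_likelihood(n, "")

    def test_ext_from_mean_length(self):
        ext = mean_length_to_ext(99.0)
        assert ext / (1 - ext) == pytest.approx(99.0)


class TestSampling:
    def test_sample_contains_w_matches_and_is_finite(self):
        h = build_hmm(4, np.full(20, 0.05), np.random.default_rng(0), mean_length=20)
        rng = np.random.default_rng(1)
        lens = [len(h.sample(rng)) for _ in range(50)]
        assert min(lens) >= 4
        assert 10 < np.mean(lens) < 40
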