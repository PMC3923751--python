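import numpy as np
import pytest

from dismotif.motifhmm import (EStats, NullModel, build_hmm, forward_batch,
                               null_log_likelihood)
from dismotif.synthgen import PlantSpec, generate
from dismotif.train import (MMIEState, TrainingConfig, baum_welch, best_of_inits,
                            ebw_step, estimate_null, extended_baum_welch,
                            mmie_objective, undersample_negatives)


def _planted_two_class(seed=0, n=30, peak=0.7, overlap=True):
    """Two classes whose planted motifs share their first two columns, so
    only discriminative training can exploit the distinguishing tail."""
    def pwm(cols):
        p = np.full((4, 20), (1 - peak) / 19)
        for j, a in enumerate(cols):
            p[j, a] = peak
        return p
    cols_b = [0, 5, 12, 17] if overlap else [2, 7, 12, 17]
    spec = PlantSpec({"a": pwm([0, 5, 10, 15]), "b": pwm(cols_b)},
                     {"a": n, "b": n}, length_range=(40, 80), seed=seed)
    d, _ = generate(spec)
    pos = [s.residues for s in d if s.label == "a"]
    neg = [s.residues for s in d if s.label == "b"]
    return pos, neg


class TestBaumWelch:
    def test_likelihood_ascent_on_repeated_sequence(self):
        seqs = ["ACDEFGHIKLMNP"] * 5
        h0 = build_hmm(4, np.full(20, 0.05), np.random.default_rng(0), mean_length=13)
        h = baum_welch(h0, seqs, max_iter=20, tol=0.0)
        tr = h.meta["ll_trace"]
        assert all(tr[i + 1] >= tr[i] - 1e-8 for i in range(len(tr) - 1))

    def test_max_iter_zero_returns_model_unchanged(self):
        h0 = build_hmm(2, np.full(20, 0.05), np.random.default_rng(1))
        h = baum_welch(h0, ["ACDEF"], max_iter=0)
        assert np.array_equal(h.match_emis, h0.match_emis)
        assert np.array_equal(h.trans, h0.trans)

    def test_empty_training_set_rejected(self):
        h0 = build_hmm(2, np.full(20, 0.05), np.random.default_rng(1))
        with pytest.raises(ValueError):
            baum_welch(h0, [], max_iter=5)

    def test_parameter_recovery_from_known_model(self):
        """Training on sequences sampled from a known motif HMM recovers
        the match emissions to small total-variation distance."""
        truth = build_hmm(3, np.full(20, 0.05), np.random.default_rng(2), mean_length=50)
        truth.match_emis = np.full((3, 20), 0.2 / 19)
        for j, a in enumerate([3, 8, 16]):
            truth.match_emis[j, a] = 0.8
        rng = np.random.default_rng(3)
        seqs = [truth.sample(rng) for _ in range(200)]
        cfg = TrainingConfig(W=3, n_init=8, max_iter=50, tol=1e-4)
        h = best_of_inits(seqs, cfg, np.random.default_rng(4))
        tv = 0.5 * np.abs(h.match_emis - truth.match_emis).sum(axis=1)
        assert tv.mean() < 0.1


class TestBestOfInits:
    def test_single_init_equals_plain_baum_welch(self):
        seqs = ["ACDEFGHIK", "MNPQRSTVW", "ACDEFGHIK"]
        cfg = TrainingConfig(W=2, n_init=1, max_iter=10, tol=1e-4)
        null = estimate_null(seqs)
        mean_len = float(np.mean([len(s) for s in seqs]))
        rng = np.random.default_rng(5)
        h0 = build_hmm(2, null.bg, rng, mean_length=mean_len, meta={"init_index": 0})
        h0.null = null
        expected = baum_welch(h0, seqs, max_iter=10, tol=1e-4, eps=cfg.eps)
        got = best_of_inits(seqs, cfg, np.random.default_rng(5))
        assert np.allclose(got.match_emis, expected.match_emis)

    def test_winner_dominates_every_restart(self):
        seqs = ["ACDEFGHIKLM", "NPQRSTVWYAC", "DEFGHIKLMNP", "QRSTVWYACDE"]
        cfg = TrainingConfig(W=2, n_init=5, max_iter=10, tol=1e-4)
        rng = np.random.default_rng(6)
        best = best_of_inits(seqs, cfg, rng)
        # re-run the restarts individually with the same stream
        null = estimate_null(seqs)
        mean_len = float(np.mean([len(s) for s in seqs]))
        rng2 = np.random.default_rng(6)
        lls = []
        for i in range(5):
            h0 = build_hmm(2, null.bg, rng2, mean_length=mean_len)
            h0.null = null
            lls.append(baum_welch(h0, seqs, 10, 1e-4).meta["final_ll"])
        assert best.meta["final_ll"] == pytest.approx(max(lls))


class TestMMIEObjective:
    def _state(self, seed=0):
        pos, neg = _planted_two_class(seed)
        null = estimate_null(pos + neg)
        h = build_hmm(4, null.bg, np.random.default_rng(seed), mean_length=60)
        h.null = null
        return MMIEState(h, null), pos, neg

    def test_matches_definitional_computation(self):
        st, pos, neg = self._state()
        lp = forward_batch(st.lambda_pos, pos + neg)
        ln = np.array([null_log_likelihood(st.competing, s) for s in pos + neg])
        m = lp - ln  # uniform priors cancel
        expected = float(-np.logaddexp(0, -m[: len(pos)]).sum()
                         - np.logaddexp(0, m[len(pos):]).sum())
        assert mmie_objective(st, pos, neg) == pytest.approx(expected, rel=1e-12)
        assert mmie_objective(st, pos, neg) <= 0

    def test_empty_negative_reduces_to_positive_terms(self):
        st, pos, _ = self._state()
        lp = forward_batch(st.lambda_pos, pos)
        ln = np.array([null_log_likelihood(st.competing, s) for s in pos])
        expected = float(-np.logaddexp(0, -(lp - ln)).sum())
        assert mmie_objective(st, pos, []) == pytest.approx(expected, rel=1e-12)

    def test_empty_positive_rejected(self):
        st, pos, neg = self._state()
        with pytest.raises(ValueError):
            mmie_objective(st, [], neg)


class TestUndersample:
    def test_size_contracts(self):
        rng = np.random.default_rng(0)
        neg = [f"s{i}" for i in range(1000)]
        out = undersample_negatives(neg, 50, rng)
        assert len(out) == 50 and len(set(out)) == 50
        assert undersample_negatives(neg[:10], 50, rng) == neg[:10]

    def test_fresh_draw_each_call_but_reproducible_under_reset(self):
        neg = [f"s{i}" for i in range(200)]
        rng = np.random.default_rng(1)
        draws = [tuple(undersample_negatives(neg, 20, rng)) for _ in range(100)]
        assert len(set(draws)) == 100  # essentially never repeats
        again = [tuple(undersample_negatives(neg, 20, np.random.default_rng(1)))]
        assert again[0] == draws[0]


class TestExtendedBaumWelch:
    def test_huge_smoothing_is_a_fixed_point(self):
        pos, neg = _planted_two_class()
        null = estimate_null(pos + neg)
        h = build_hmm(4, null.bg, np.random.default_rng(0), mean_length=60)
        h.null = null
        num = _stats_of(h, pos)
        den = _stats_of(h, pos + neg, 0.5)
        cfg = TrainingConfig(W=4, ebw_c=1e9)
        h2 = ebw_step(h, num, den, cfg)
        assert np.allclose(h2.match_emis, h.match_emis, atol=1e-5)
        assert np.allclose(h2.trans, h.trans, atol=1e-5)

    def test_zero_denominator_and_vanishing_d_equals_mle_update(self):
        from dismotif.train import _mstep
        pos, _ = _planted_two_class(n=5)
        null = estimate_null(pos)
        h = build_hmm(4, null.bg, np.random.default_rng(1), mean_length=60)
        h.null = null
        num = _stats_of(h, pos)
        zero = EStats(np.zeros_like(num.init), np.zeros_like(num.trans),
                      np.zeros_like(num.emis), 0.0, None)
        cfg = TrainingConfig(W=4, ebw_c=1e-9)
        disc = ebw_step(h, num, zero, cfg)
        gen = _mstep(h, num, cfg.eps)
        assert np.allclose(disc.match_emis, gen.match_emis, atol=1e-4)

    def test_objective_increases_and_distributions_stay_valid(self):
        pos, neg = _planted_two_class(seed=0)
        cfg = TrainingConfig(W=4, n_init=5, max_iter=30, tol=1e-3)
        null = estimate_null(pos + neg)
        h = best_of_inits(pos, cfg, np.random.default_rng(11), null=null)
        st0 = MMIEState(h, null)
        obj0 = mmie_objective(st0, pos, neg)
        st = extended_baum_welch(st0, pos, neg, cfg, np.random.default_rng(12))
        assert mmie_objective(st, pos, neg) > obj0
        st.lambda_pos.validate(atol=1e-9)
        assert st.lambda_pos.match_emis.min() >= cfg.eps / 2
        assert st.trace[0] == pytest.approx(obj0)

    def test_discrimination_gap_widens_after_ebw(self):
        """On overlapping planted motifs the mean positive-negative LLR
        separation grows under discriminative refinement."""
        pos, neg = _planted_two_class(seed=0)
        cfg = TrainingConfig(W=4, n_init=5, max_iter=30, tol=1e-3)
        null = estimate_null(pos + neg)
        h_gen = best_of_inits(pos, cfg, np.random.default_rng(11), null=null)
        st = extended_baum_welch(MMIEState(h_gen, null), pos, neg, cfg,
                                 np.random.default_rng(12))

        def gap(h):
            lls = forward_batch(h, pos + neg)
            nll = np.array([null_log_likelihood(h.null, s) for s in pos + neg])
            llr = lls - nll
            return llr[: len(pos)].mean() - llr[len(pos):].mean()

        assert gap(st.lambda_pos) > gap(h_gen)

    def test_undersampling_noop_when_negatives_match_positives(self):
        """With |neg| == |pos| the under-sampled run equals the full run
        given identical seeds (the sampler returns everything)."""
        pos, neg = _planted_two_class(n=10)
        cfg_a = TrainingConfig(W=4, n_init=2, max_iter=5, undersample=True)
        cfg_b = TrainingConfig(W=4, n_init=2, max_iter=5, undersample=False)
        null = estimate_null(pos + neg)
        h = best_of_inits(pos, cfg_a, np.random.default_rng(3), null=null)
        st_a = extended_baum_welch(MMIEState(h, null), pos, neg, cfg_a,
                                   np.random.default_rng(4))
        st_b = extended_baum_welch(MMIEState(h, null), pos, neg, cfg_b,
                                   np.random.default_rng(4))
        assert np.array_equal(st_a.lambda_pos.match_emis, st_b.lambda_pos.match_emis)


def _stats_of(h, seqs, weight=None):
    from dismotif.motifhmm import expected_counts
    w = None if weight is None else np.full(len(seqs), weight)
    return expected_counts(h, seqs, weights=w)


class TestConfig:
    def test_defaults_are_reference_settings(self):
        cfg = TrainingConfig()
        assert (cfg.W, cfg.n_init, cfg.max_iter) == (4, 10, 50)
        assert cfg.mutation_rate == 0.2 and cfg.n_motifs_per_class == 10
        assert cfg.svm_c == 0.01 and cfg.n_folds == 10

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(mutation_rate=1.5)
        with pytest.raises(ValueError):
            TrainingConfig(structure="ring")
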