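"""Emission scorers: linear baseline, deep scorer, training, refiner."""

import numpy as np
import pytest

import crfthread as ct
from crfthread.crf import loglik, loglik_grad_theta
from crfthread.distance import N_BINS
from crfthread.drnf import (
    DrnfConfig,
    DrnfScorer,
    LinearScorer,
    RefinerScorer,
    build_refiner_input,
    load_checkpoint,
    save_checkpoint,
    train_mle,
    _length_product_batches,
)
from crfthread.features import pair_features, query_seq_features, template_seq_features

SMALL = DrnfConfig(conv1d_layers=3, res2d_blocks=1, convs_per_block=2,
                   width1d=4, width2d=6, kernel2d=3)


@pytest.fixture(scope="module")
def qt(small_fixture):
    return small_fixture.query, small_fixture.template


class TestLinearScorer:
    def test_zero_weights_zero_scores(self, qt):
        th = LinearScorer().score(*qt)
        assert np.all(th.theta == 0.0)

    def test_identity_weight_identical_sequences(self):
        fx = ct.make_pair(ct.sample_fold(6, 0), 0.0, 0.0, 0.0, seed=1)
        sc = LinearScorer()
        sc.w.value[0] = 1.0
        th = sc.score(fx.query, fx.template)
        assert np.allclose(np.diag(th.theta[:, :, 0]), 1.0)

    def test_affine_in_weights(self, qt):
        feats = pair_features(*qt)
        rng = np.random.default_rng(0)
        w1, w2 = rng.normal(size=(2, 9))
        out = {}
        for key, w in (("a", w1), ("b", w2), ("sum", w1 + 2 * w2)):
            sc = LinearScorer()
            sc.w.value[:] = w
            out[key] = sc.score_features(feats).theta[:, :, 0]
        assert np.allclose(out["sum"], out["a"] + 2 * out["b"], atol=1e-10)

    def test_gap_channels_constant(self, qt):
        sc = LinearScorer(gap_ix=-1.5, gap_iy=-0.7)
        th = sc.score(*qt).theta
        assert np.all(th[:, :, 1] == -1.5) and np.all(th[:, :, 2] == -0.7)
        assert np.all(th[:, :, 3:] == 0.0)


def naive_drnf_forward(scorer, q, t):
    """Independent re-evaluation of the deep scorer's layer sequence using
    plain loops (no im2col, no shared code paths)."""

    def conv1d(x, W, b):
        k = W.shape[0]
        pad = k // 2
        xp = np.pad(x, ((pad, pad), (0, 0)))
        out = np.zeros((x.shape[0], W.shape[2]))
        for pos in range(x.shape[0]):
            for d in range(k):
                out[pos] += xp[pos + d] @ W[d]
        return out + b

    def conv2d(x, W, b):
        k = W.shape[0]
        pad = k // 2
        xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
        out = np.zeros(x.shape[:2] + (W.shape[3],))
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                for a in range(k):
                    for bb in range(k):
                        out[i, j] += xp[i + a, j + bb] @ W[a, bb]
        return out + b

    def instnorm(x, gamma, beta, eps=1e-5):
        axes = tuple(range(x.ndim - 1))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        return gamma * (x - mu) / np.sqrt(var + eps) + beta

    from crfthread import nn

    def run(seq, x):
        for m in seq.modules:
            if isinstance(m, nn.Conv1D):
                x = conv1d(x, m.W.value, m.b.value)
            elif isinstance(m, nn.Conv2D):
                x = conv2d(x, m.W.value, m.b.value)
            elif isinstance(m, nn.InstanceNorm):
                x = instnorm(x, m.gamma.value, m.beta.value)
            elif isinstance(m, nn.ReLU):
                x = np.maximum(x, 0.0)
            elif isinstance(m, nn.ResidualBlock):
                x = run(m.body, x) + x
            else:
                raise AssertionError(f"unexpected module {m}")
        return x

    ft = run(scorer.net1d_t, template_seq_features(t))
    fq = run(scorer.net1d_q, query_seq_features(q))
    pf = pair_features(q, t).channels
    n1, n2, w = ft.shape[0], fq.shape[0], ft.shape[1]
    x2d = np.concatenate(
        [np.broadcast_to(ft[:, None, :], (n1, n2, w)),
         np.broadcast_to(fq[None, :, :], (n1, n2, w)), pf], axis=2)
    return run(scorer.net2d, x2d)[:, :, 0]


class TestDrnfScorer:
    def test_zero_parameters_zero_scores(self, qt):
        sc = DrnfScorer(SMALL, seed=0)
        for _n, p in sc.parameters():
            p.value[...] = 0.0
        assert np.all(sc.score(*qt).theta == 0.0)

    def test_deterministic(self, qt):
        a = DrnfScorer(SMALL, seed=5).score(*qt).theta
        b = DrnfScorer(SMALL, seed=5).score(*qt).theta
        assert np.array_equal(a, b)

    def test_matches_independent_forward(self, qt):
        sc = DrnfScorer(SMALL, seed=3)
        got = sc.score(*qt).theta[:, :, 0]
        expected = naive_drnf_forward(sc, *qt)
        assert np.allclose(got, expected, atol=1e-10)

    def test_query_permutation_equivariance_at_kernel_one(self):
        # with kernel size 1 there is no sequential context, so permuting
        # query positions must permute the score columns
        cfg = DrnfConfig(conv1d_layers=2, kernel1d=1, res2d_blocks=1,
                         convs_per_block=1, kernel2d=1, width1d=4, width2d=4,
                         use_norm=False)
        fx = ct.make_pair(ct.sample_fold(7, 1), 0.2, 0.0, 0.2, seed=2)
        q, t = fx.query, fx.template
        sc = DrnfScorer(cfg, seed=1)
        base = sc.score(q, t).theta[:, :, 0]
        perm = np.array([2, 0, 1, 4, 3, 6, 5])
        qp = ct.QueryRecord("".join(q.sequence[i] for i in perm), q.psfm[perm],
                            q.pssm[perm], q.ss3[perm], q.ss8[perm], q.acc[perm])
        swapped = sc.score(qp, t).theta[:, :, 0]
        assert np.allclose(swapped, base[:, perm], atol=1e-10)

    def test_gap_emission_mode(self, qt):
        cfg = DrnfConfig(conv1d_layers=2, res2d_blocks=1, convs_per_block=1,
                         width1d=3, width2d=4, kernel2d=3, emit_gap_scores=True)
        th = DrnfScorer(cfg, seed=0).score(*qt).theta
        assert not np.all(th[:, :, 1] == th[0, 0, 1])  # position-dependent

    def test_checkpoint_round_trip(self, qt, tmp_path):
        sc = DrnfScorer(SMALL, seed=9)
        save_checkpoint(tmp_path / "m.npz", sc)
        back = load_checkpoint(tmp_path / "m.npz")
        assert np.array_equal(back.score(*qt).theta, sc.score(*qt).theta)


class TestTraining:
    def test_gradient_matches_finite_differences(self):
        fx = ct.make_pair(ct.sample_fold(5, 42), 0.3, 0.0, 0.2, seed=7)
        q, t, ref = fx.query, fx.template, fx.reference
        sc = LinearScorer()
        sc.w.value[:] = np.linspace(0.1, 0.9, 9)
        sc.gap.value[:] = [-0.4, -0.6]
        theta, cache = sc.score_and_cache(q, t)
        _, g = loglik_grad_theta(ref, theta)
        sc.zero_grad()
        sc.backward(cache, g)
        eps = 1e-5
        for _name, p in sc.parameters():
            for idx in np.ndindex(*p.value.shape):
                orig = p.value[idx]
                p.value[idx] = orig + eps
                lp = loglik(ref, sc.score(q, t))
                p.value[idx] = orig - eps
                lm = loglik(ref, sc.score(q, t))
                p.value[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - p.grad[idx]) <= 1e-4 * max(1.0, abs(fd))

    def test_deep_scorer_directional_gradient(self):
        fx = ct.make_pair(ct.sample_fold(5, 42), 0.3, 0.0, 0.2, seed=7)
        q, t, ref = fx.query, fx.template, fx.reference
        sc = DrnfScorer(SMALL, seed=3)
        theta, cache = sc.score_and_cache(q, t)
        _, g = loglik_grad_theta(ref, theta)
        sc.zero_grad()
        sc.backward(cache, g)
        rng = np.random.default_rng(9)
        direction = {n: rng.normal(size=p.value.shape) for n, p in sc.parameters()}
        analytic = sum((p.grad * direction[n]).sum() for n, p in sc.parameters())
        eps = 1e-6
        for n, p in sc.parameters():
            p.value += eps * direction[n]
        lp = loglik(ref, sc.score(q, t))
        for n, p in sc.parameters():
            p.value -= 2 * eps * direction[n]
        lm = loglik(ref, sc.score(q, t))
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - analytic) <= 1e-5 * max(1.0, abs(fd))

    def test_zero_epochs_leaves_params_unchanged(self, small_fixture):
        pairs = [(small_fixture.query, small_fixture.template, small_fixture.reference)]
        sc = LinearScorer()
        sc.w.value[:] = 0.3
        before = sc.w.value.copy()
        train_mle(pairs, sc, epochs=0)
        assert np.array_equal(sc.w.value, before)

    def test_full_batch_ascent_is_monotone(self):
        rng = np.random.default_rng(2)
        pairs = []
        for k in range(6):
            fx = ct.make_pair(ct.sample_fold(8, 50 + k), 0.2, 0.1, 0.1, seed=k)
            pairs.append((fx.query, fx.template, fx.reference))
        sc = LinearScorer()
        _, history = train_mle(pairs, sc, epochs=10, lr=1e-3,
                               batch_budget=10**9, optimizer="sgd")
        assert all(b >= a - 1e-9 for a, b in zip(history, history[1:]))

    def test_length_product_batching(self):
        fxs = [ct.make_pair(ct.sample_fold(n, n), 0.1, 0.0, 0.1, seed=n)
               for n in (4, 6, 8, 10)]
        pairs = [(f.query, f.template, f.reference) for f in fxs]
        batches = _length_product_batches(pairs, budget=120)
        assert sorted(k for b in batches for k in b) == [0, 1, 2, 3]
        for b in batches:
            load = sum(len(pairs[k][0]) * len(pairs[k][1]) for k in b)
            assert len(b) == 1 or load <= 120

    def test_divergence_detected(self, small_fixture):
        pairs = [(small_fixture.query, small_fixture.template, small_fixture.reference)]
        sc = LinearScorer()
        sc.bias.value[0] = 1e308  # forces overflow in the partition function
        with pytest.raises(FloatingPointError):
            train_mle(pairs, sc, epochs=1)


class TestRefiner:
    def _instance(self, seed=0, n=8):
        fx = ct.make_pair(ct.sample_fold(n, seed), 0.3, 0.1, 0.1, seed=seed + 1)
        rng = np.random.default_rng(seed)
        n1, n2 = len(fx.template), len(fx.query)
        th = np.zeros((n1, n2, 5))
        th[:, :, 0] = rng.normal(size=(n1, n2))
        u = rng.normal(size=(n2, n2, N_BINS))
        u = (u + u.transpose(1, 0, 2)) / 2.0
        tb = ct.template_distance_bins(fx.template.dist)
        return fx, th, u, tb

    def test_single_pair_masked_sum(self):
        fx, th, u, tb = self._instance(3)
        n1, n2 = th.shape[:2]
        k, l = sorted(ct.aligned_pairs(fx.reference))[1]
        init = ct.alignment_from_pairs([(k, l)], n1, n2)
        rin = build_refiner_input(init, th, u, tb, tdist=fx.template.dist)
        pot = rin.channels[:, :, 2]
        for i in range(n1):
            for j in range(n2):
                if i == k or j == l:
                    assert pot[i, j] == 0.0
                elif fx.template.dist[i, k] < 16.0:
                    assert pot[i, j] == pytest.approx(-u[j, l, tb[i, k]])
                else:
                    assert pot[i, j] == 0.0

    def test_all_beyond_cutoff_zero_channel(self):
        fx, th, u, _ = self._instance(4)
        n1, n2 = th.shape[:2]
        tb = np.full((n1, n1), N_BINS - 1)
        np.fill_diagonal(tb, 0)
        rin = build_refiner_input(fx.reference, th, u, tb)
        assert np.all(rin.channels[:, :, 2] == 0.0)

    def test_matches_brute_force_double_loop(self):
        fx, th, u, tb = self._instance(5)
        rin = build_refiner_input(fx.reference, th, u, tb)
        pairs = ct.aligned_pairs(fx.reference)
        n1, n2 = th.shape[:2]
        expected = np.zeros((n1, n2))
        for i in range(n1):
            for j in range(n2):
                for (k, l) in pairs:
                    if k != i and l != j and tb[i, k] < N_BINS - 1:
                        expected[i, j] += -u[j, l, tb[i, k]]
        assert np.allclose(rin.channels[:, :, 2], expected, atol=1e-10)
        assert np.array_equal(rin.channels[:, :, 1], th[:, :, 0])
        ind = rin.channels[:, :, 0]
        assert set(zip(*np.nonzero(ind))) == pairs

    def test_refiner_scorer_contract(self):
        fx, th, u, tb = self._instance(6)
        rin = build_refiner_input(fx.reference, th, u, tb)
        sc = RefinerScorer(SMALL, seed=0)
        out1 = sc.score(rin).theta
        out2 = RefinerScorer(SMALL, seed=0).score(rin).theta
        assert np.array_equal(out1, out2)
        for _n, p in sc.parameters():
            p.value[...] = 0.0
        assert np.all(sc.score(rin).theta == 0.0)
        a, _ = ct.viterbi(out1)
        a.validate()
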