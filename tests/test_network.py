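"""Network laws: attention normalisation, GRU recurrence against an
independent step-by-step oracle, the full hierarchical forward against a
straight-line reimplementation, evidential-loss identities, and training
behaviour (determinism, loss descent, multilabel freedom)."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit

from carenet.network import (CareNetClassifier, attention_pool,
                             encode_sequence, evidential_loss, forward,
                             init_params)

# --------------------------------------------------------------------------
# independent oracles (plain numpy, no autodiff)
# --------------------------------------------------------------------------


def oracle_gru(X, Wx, Wh, b, reverse=False):
    """Step-by-step GRU recurrence coded directly from the update
    equations; one (T, D) sequence, returns (T, H)."""
    T = X.shape[0]
    H = Wh.shape[0]
    h = np.zeros(H)
    out = np.zeros((T, H))
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        g = X[t] @ Wx + b
        gh = h @ Wh
        r = expit(g[:H] + gh[:H])
        z = expit(g[H:2 * H] + gh[H:2 * H])
        n = np.tanh(g[2 * H:] + r * gh[2 * H:])
        h = (1 - z) * n + z * h
        out[t] = h
    return out


def oracle_bigru(X, params, prefix):
    fwd = oracle_gru(X, params[f"{prefix}f_wx"].data, params[f"{prefix}f_wh"].data,
                     params[f"{prefix}f_b"].data)
    bwd = oracle_gru(X, params[f"{prefix}b_wx"].data, params[f"{prefix}b_wh"].data,
                     params[f"{prefix}b_b"].data, reverse=True)
    return np.concatenate([fwd, bwd], axis=1)


def oracle_attention(H, params, prefix):
    u = np.tanh(H @ params[f"{prefix}_w"].data + params[f"{prefix}_b"].data)
    logits = (u @ params[f"{prefix}_q"].data).ravel()
    e = np.exp(logits - logits.max())
    a = e / e.sum()
    return a, a @ H


def oracle_forward(params, tok, tmask, cmask, pnum, onsite):
    """Loop-free-of-abstractions reimplementation of the full hierarchy for
    a single visit (B=1)."""
    _, M, C, L = tok.shape
    E = params["embed"].data
    cells = np.zeros((M, C, params["empty_ctx"].data.shape[1]))
    for p in range(M):
        for c in range(C):
            n = int(tmask[0, p, c].sum())
            if n == 0:
                cells[p, c] = params["empty_ctx"].data[c]
                continue
            X = E[tok[0, p, c, :n]]
            H1 = oracle_bigru(X, params, "gru1")
            _, cells[p, c] = oracle_attention(H1, params, "att1")
    periods = np.zeros((M, cells.shape[2] + pnum.shape[2]))
    for p in range(M):
        H2 = oracle_bigru(cells[p], params, "gru2")
        _, s2 = oracle_attention(H2, params, "att2")
        periods[p] = np.concatenate([s2, pnum[0, p]])
    H3 = oracle_bigru(periods, params, "gru3")
    _, s3 = oracle_attention(H3, params, "att3")
    patient = np.concatenate([s3, onsite[0]])
    f1 = np.tanh(patient @ params["ffn_w1"].data + params["ffn_b1"].data)
    ev = np.logaddexp(0.0, f1 @ params["ffn_w2"].data + params["ffn_b2"].data)
    return ev[:4], ev[4:]


def tiny_params(rng, vocab_size=6, d=2, H=2, A=2, P=1, Q=2, F=3):
    return init_params(vocab_size, embed_dim=d, hidden=H, attn_dim=A,
                       n_period_numeric=P, n_onsite=Q, ffn_dim=F, rng=rng)


# --------------------------------------------------------------------------
# attention block
# --------------------------------------------------------------------------


class TestAttention:
    def test_identical_states_get_uniform_weights(self, rng):
        params = tiny_params(rng, H=3, A=4)
        h = np.tile(rng.normal(size=(1, 6)), (5, 1))
        res = attention_pool(h, params, "att1")
        np.testing.assert_allclose(res.weights, np.full(5, 0.2), atol=1e-12)

    def test_single_state_gets_weight_one(self, rng):
        params = tiny_params(rng, H=3, A=4)
        h = rng.normal(size=(1, 6))
        res = attention_pool(h, params, "att1")
        assert res.weights[0] == pytest.approx(1.0)
        np.testing.assert_allclose(res.pooled, h[0])

    def test_two_term_softmax_oracle(self, rng):
        params = tiny_params(rng, H=2, A=2)
        h = rng.normal(size=(2, 4))
        res = attention_pool(h, params, "att1")
        a, s = oracle_attention(h, params, "att1")
        np.testing.assert_allclose(res.weights, a, atol=1e-12)
        np.testing.assert_allclose(res.pooled, s, atol=1e-12)

    def test_pooled_is_weighted_sum(self, rng):
        params = tiny_params(rng, H=4, A=3)
        h = rng.normal(size=(7, 8))
        res = attention_pool(h, params, "att1")
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.pooled, res.weights @ h, atol=1e-9)

    def test_empty_input_rejected(self, rng):
        params = tiny_params(rng)
        with pytest.raises(ValueError):
            attention_pool(np.zeros((0, 4)), params, "att1")


# --------------------------------------------------------------------------
# encoder
# --------------------------------------------------------------------------


class TestEncoder:
    @pytest.mark.parametrize("T", [1, 2, 7])
    def test_shape_contract(self, rng, T):
        params = tiny_params(rng, d=3, H=4)
        out = encode_sequence(rng.normal(size=(T, 3)), params, "gru1")
        assert out.shape == (T, 8)
        assert np.isfinite(out).all()

    def test_zero_input_zero_weights_give_zero(self, rng):
        params = tiny_params(rng, d=3, H=2)
        for k in params:
            if k.startswith("gru1"):
                params[k].data[:] = 0.0
        out = encode_sequence(np.zeros((4, 3)), params, "gru1")
        np.testing.assert_allclose(out, 0.0)

    def test_matches_step_by_step_recurrence_oracle(self, rng):
        params = tiny_params(rng, d=2, H=2)
        X = rng.normal(size=(2, 2))
        out = encode_sequence(X, params, "gru1")
        np.testing.assert_allclose(out, oracle_bigru(X, params, "gru1"),
                                   atol=1e-10)

    def test_rejects_nonfinite(self, rng):
        params = tiny_params(rng)
        with pytest.raises(ValueError, match="non-finite"):
            encode_sequence(np.array([[np.nan, 0.0]]), params, "gru1")


# --------------------------------------------------------------------------
# full forward
# --------------------------------------------------------------------------


def _tiny_batch(rng, M=2, C=6, L=3):
    tok = rng.integers(2, 6, size=(1, M, C, L))
    lens = rng.integers(0, L + 1, size=(1, M, C))
    tmask = (np.arange(L)[None, None, None, :] < lens[..., None]).astype(float)
    tok = tok * (tmask.astype(int))
    cmask = (lens > 0).astype(float)
    pnum = rng.normal(size=(1, M, 2))    # one variable: value ++ indicator
    onsite = rng.normal(size=(1, 4))     # two variables: values ++ indicators
    return tok, tmask, cmask, pnum, onsite


def test_forward_matches_straight_line_oracle(rng):
    """The batched hierarchical forward equals an independently coded
    single-visit reimplementation on tiny fixed parameters."""
    for trial in range(5):
        params = tiny_params(rng)
        tok, tmask, cmask, pnum, onsite = _tiny_batch(rng)
        e_pos, e_neg, _ = forward(params, tok, tmask, cmask, pnum, onsite)
        o_pos, o_neg = oracle_forward(params, tok, tmask, cmask, pnum, onsite)
        np.testing.assert_allclose(e_pos.data[0], o_pos, atol=1e-6)
        np.testing.assert_allclose(e_neg.data[0], o_neg, atol=1e-6)


def test_all_empty_bundle_is_finite_and_symmetric(rng):
    params = tiny_params(rng)
    M, C, L = 3, 6, 1
    tok = np.zeros((1, M, C, L), dtype=int)
    tmask = np.zeros((1, M, C, L))
    cmask = np.zeros((1, M, C))
    pnum = np.tile(rng.normal(size=(1, 1, 2)), (1, M, 1))  # identical periods
    onsite = rng.normal(size=(1, 4))
    e_pos, e_neg, trace = forward(params, tok, tmask, cmask, pnum, onsite,
                                  capture=True)
    assert np.isfinite(e_pos.data).all() and np.isfinite(e_neg.data).all()
    # identical period inputs: the recurrent encoder still injects position
    # information, so exact uniformity is not implied — the weights must be
    # a valid near-uniform distribution at small random init
    assert trace["period_attn"][0].sum() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(trace["period_attn"][0], np.full(M, 1 / M),
                               atol=0.05)


def test_attention_groups_and_convex_hull(small_bundles):
    """On real visits: every attention group sums to 1 and every pooled
    vector is the attention-weighted sum of its hidden states."""
    from carenet.network import _collate, pack_visit

    clf = CareNetClassifier(n_epochs=1, random_state=0)
    clf.fit(small_bundles[:40])
    packed = [pack_visit(b, clf.scaler_, clf.max_events_per_cell)
              for b in small_bundles[:20]]
    tok, tmask, cmask, pnum, onsite, _ = _collate(packed)
    _, _, tr = forward(clf.params_, tok, tmask, cmask, pnum, onsite, capture=True)
    B, M, C, L = tok.shape
    ev_sums = tr["event_attn"].sum(axis=3)
    assert np.allclose(ev_sums[cmask > 0], 1.0, atol=1e-5)
    assert np.allclose(ev_sums[cmask == 0], 0.0, atol=1e-12)
    assert np.allclose(tr["context_attn"].sum(axis=2), 1.0, atol=1e-5)
    assert np.allclose(tr["period_attn"].sum(axis=1), 1.0, atol=1e-5)
    # pooled = sum of weights times hidden states, at every level
    ev_pool = np.einsum("bmcl,bmclh->bmch", tr["event_attn"], tr["event_hidden"])
    assert np.allclose(ev_pool[cmask > 0], tr["event_pooled"][cmask > 0], atol=1e-6)
    ctx_pool = np.einsum("bmc,bmch->bmh", tr["context_attn"], tr["context_hidden"])
    assert np.allclose(ctx_pool, tr["context_pooled"], atol=1e-6)
    per_pool = np.einsum("bm,bmh->bh", tr["period_attn"], tr["period_hidden"])
    assert np.allclose(per_pool, tr["period_pooled"], atol=1e-6)


def test_period_permutation_changes_output_event_order_does_not(rng, small_vocab):
    import pandas as pd
    from carenet.ehr import Context, EventRecord, IndexVisit, TimelineConfig, build_bundle

    t0 = pd.Timestamp("2020-06-01")
    visit = IndexVisit("v", "p", t0, onsite=np.zeros(3), onsite_mask=np.ones(3),
                       onsite_names=["age", "sex", "temp"],
                       main_dx_codes=["I50.9"])
    mk = lambda d, code: EventRecord("p", "v", t0 - pd.Timedelta(days=d),
                                     Context.ED, code)
    evs = [mk(3, "RX:C000"), mk(3, "RX:C005"), mk(100, "PROC:K002")]
    cfg = TimelineConfig()
    b1 = build_bundle(evs, visit, small_vocab, cfg)
    b2 = build_bundle([evs[1], evs[2], evs[0]], visit, small_vocab, cfg)
    other_visit = IndexVisit("v2", "p2", t0, onsite=np.zeros(3),
                             onsite_mask=np.ones(3),
                             onsite_names=["age", "sex", "temp"],
                             main_dx_codes=["R06.0"])
    b_other = build_bundle([mk(30, "DX:Z004")], other_visit, small_vocab, cfg)

    clf = CareNetClassifier(n_epochs=1, random_state=3)
    clf.fit([b1, b2, b_other, b_other], vocab_size=len(small_vocab))
    p1 = clf.predict_proba([b1])
    p2 = clf.predict_proba([b2])
    np.testing.assert_allclose(p1, p2, atol=1e-12)  # canonicalised input order
    # permuting periods (time reversal) changes the prediction
    b3 = build_bundle([mk(100, "RX:C000"), mk(100, "RX:C005"),
                       mk(3, "PROC:K002")], visit, small_vocab, cfg)
    p3 = clf.predict_proba([b3])
    assert np.abs(p1 - p3).max() > 1e-8


# --------------------------------------------------------------------------
# evidential head and loss
# --------------------------------------------------------------------------


class TestEvidentialLoss:
    def test_zero_evidence_is_maximal_uncertainty(self):
        from carenet.network import EvidentialOutput

        out = EvidentialOutput(e_pos=np.zeros((1, 4)), e_neg=np.zeros((1, 4)))
        np.testing.assert_allclose(out.prob, 0.5)
        np.testing.assert_allclose(out.uncertainty, 1.0)

    def test_loss_vanishes_with_infinite_correct_evidence(self):
        losses = [evidential_loss([e], [0.0], [1.0], lam=1.0)
                  for e in (10.0, 100.0, 1000.0)]
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-2

    def test_bayes_risk_identity_alpha2_beta1(self):
        """alpha=2, beta=1, y=1, lam=0: the loss equals the numerically
        integrated Bayes risk of the squared error under Beta(2, 1)."""
        val = evidential_loss([1.0], [0.0], [1.0], lam=0.0)
        num, _ = integrate.quad(lambda p: (1 - p) ** 2 * stats.beta.pdf(p, 2, 1),
                                0, 1)
        assert val == pytest.approx(1 / 6, abs=1e-12)
        assert val == pytest.approx(num, abs=1e-6)

    def test_negative_evidence_rejected(self):
        with pytest.raises(ValueError):
            evidential_loss([-0.1], [0.0], [1.0])
        with pytest.raises(ValueError):
            evidential_loss([0.0], [0.0], [1.0], lam=1.5)

    def test_kl_projects_only_misleading_evidence(self):
        # with y=1, raising e+ must not raise the KL part
        base = evidential_loss([5.0], [0.0], [1.0], lam=1.0)
        more = evidential_loss([50.0], [0.0], [1.0], lam=1.0)
        assert more < base


def test_multilabel_scores_are_uncoupled(rng, small_bundles):
    """A visit can receive summed label probabilities above 1: no softmax
    or normalisation couples the four heads."""
    clf = CareNetClassifier(n_epochs=1, random_state=0)
    clf.fit(small_bundles[:30])
    clf.params_["ffn_b2"].data[:] = np.r_[np.full(4, 10.0), np.full(4, -10.0)]
    p = clf.predict_proba(small_bundles[:5])
    assert (p.sum(axis=1) > 1.0).all()
    assert ((p > 0) & (p < 1)).all()


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


class TestTraining:
    def test_one_epoch_trains_and_is_finite(self, small_bundles):
        clf = CareNetClassifier(n_epochs=1, random_state=0)
        clf.fit(small_bundles[:10])
        assert np.isfinite(clf.loss_curve_[0])
        assert clf.params_["ffn_w1"].data.std() > 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="no training bundles"):
            CareNetClassifier(n_epochs=1).fit([])

    def test_seed_reproducibility(self, small_bundles):
        r1 = CareNetClassifier(n_epochs=2, random_state=42).fit(small_bundles[:24])
        r2 = CareNetClassifier(n_epochs=2, random_state=42).fit(small_bundles[:24])
        assert r1.loss_curve_ == r2.loss_curve_
        np.testing.assert_array_equal(r1.params_["embed"].data,
                                      r2.params_["embed"].data)

    def test_loss_decreases(self, small_bundles):
        clf = CareNetClassifier(n_epochs=6, random_state=0)
        clf.fit(small_bundles[:60])
        assert clf.loss_curve_[-1] < clf.loss_curve_[0]

    def test_single_label_data_rejected(self, small_bundles):
        y = np.tile([0.0, 0, 0, 1], (10, 1))
        with pytest.raises(ValueError, match="two labels"):
            CareNetClassifier(n_epochs=1).fit(small_bundles[:10], y=y)


def test_checkpoint_round_trip(tmp_path, small_bundles):
    clf = CareNetClassifier(n_epochs=1, random_state=7)
    clf.fit(small_bundles[:16])
    p = clf.predict_proba(small_bundles[16:20])
    path = tmp_path / "ckpt.npz"
    clf.save(path)
    clf2 = CareNetClassifier.load(path)
    np.testing.assert_allclose(clf2.predict_proba(small_bundles[16:20]), p,
                               atol=1e-12)
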