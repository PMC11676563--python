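"""The hierarchical attention recurrent network with an evidential head.

Architecture, bottom to top, mirroring how a clinician scans a chart:

1. *Event layer* — within every (period, context) cell, event-code
   embeddings run through a bidirectional GRU and an attention pool,
   producing one care-context embedding per cell.  Cells with no events
   contribute a learned per-context "empty" embedding instead.
2. *Context layer* — the six context embeddings of a period run through a
   second biGRU + attention pool; the result is concatenated with the
   period's continuous variables (standardised, missing = 0 plus an
   observed-indicator channel) to form the period representation.
3. *Period layer* — the M period representations (period 0 = most recent)
   run through a third biGRU + attention pool; the result is concatenated
   with the onsite triage variables to form the patient representation,
   which a two-layer feed-forward head maps through softplus to eight
   non-negative evidences: (e+, e-) for each of the four labels.

Each label j gets a Beta(alpha_j, beta_j) opinion with alpha = e+ + 1,
beta = e- + 1; the reported score is the Beta mean p = alpha/(alpha+beta)
and the uncertainty u = 2/(alpha+beta).  Labels are NOT coupled by any
normalisation, so the four scores may sum to more than 1.  The loss per
label is the Bayes risk of the squared error under the Beta opinion plus
an annealed KL term that shrinks evidence not supported by the label:

    L_j = (y_j - p_j)^2 + p_j(1-p_j)/(S_j+1)
          + lambda_t * KL( Beta(1+(1-y_j)e+_j, 1+y_j e-_j) || Beta(1,1) )
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .ehr import EMPTY_ID, N_CONTEXTS, VisitTensorBundle
from sklearn.base import BaseEstimator, ClassifierMixin

LABELS = ("ahf", "ecopd", "pneumonia", "other")
N_LABELS = 4


# --------------------------------------------------------------------------
# Output containers
# --------------------------------------------------------------------------


@dataclass
class EvidentialOutput:
    """Per-label evidence pairs and the Beta-opinion summaries they induce."""

    e_pos: np.ndarray   # (n, 4) evidence for the label
    e_neg: np.ndarray   # (n, 4) evidence against

    @property
    def alpha(self):
        return self.e_pos + 1.0

    @property
    def beta(self):
        return self.e_neg + 1.0

    @property
    def strength(self):
        return self.alpha + self.beta

    @property
    def prob(self):
        return self.alpha / self.strength

    @property
    def uncertainty(self):
        return 2.0 / self.strength


@dataclass
class HierarchyState:
    """Attention weights captured during one visit's forward pass, plus the
    (possibly truncated) token ids they refer to."""

    event_attn: np.ndarray    # (M, C, L)
    context_attn: np.ndarray  # (M, C)
    period_attn: np.ndarray   # (M,)
    tokens: np.ndarray        # (M, C, L) int token ids
    token_mask: np.ndarray    # (M, C, L)
    cell_mask: np.ndarray     # (M, C) 1 if the cell had events
    visit_id: str = ""


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------


def init_params(vocab_size: int, embed_dim: int = 16, hidden: int = 16,
                attn_dim: int = 32, n_period_numeric: int = 5,
                n_onsite: int = 11, ffn_dim: int = 32,
                rng: np.random.Generator | None = None,
                init_embeddings: np.ndarray | None = None) -> dict:
    """Fresh parameter dict; GRU/attention weights use uniform(-1/sqrt(H))
    fan-in init, the embedding table optionally comes from skip-gram."""
    rng = rng or np.random.default_rng()
    H, d = hidden, embed_dim
    p: dict[str, ad.Tensor] = {}

    if init_embeddings is not None:
        E = np.array(init_embeddings, dtype=float)
        if E.shape != (vocab_size, d):
            raise ValueError(f"init embeddings shape {E.shape} != {(vocab_size, d)}")
    else:
        E = rng.normal(0.0, 0.1, size=(vocab_size, d))
    E[EMPTY_ID] = 0.0
    p["embed"] = ad.Tensor(E)
    p["empty_ctx"] = ad.Tensor(rng.normal(0.0, 0.1, size=(N_CONTEXTS, 2 * H)))

    def gru(prefix, din):
        k = 1.0 / np.sqrt(H)
        p[f"{prefix}_wx"] = ad.Tensor(rng.uniform(-k, k, size=(din, 3 * H)))
        p[f"{prefix}_wh"] = ad.Tensor(rng.uniform(-k, k, size=(H, 3 * H)))
        p[f"{prefix}_b"] = ad.Tensor(np.zeros(3 * H))

    def attn(prefix, din):
        k = 1.0 / np.sqrt(din)
        p[f"{prefix}_w"] = ad.Tensor(rng.uniform(-k, k, size=(din, attn_dim)))
        p[f"{prefix}_b"] = ad.Tensor(np.zeros(attn_dim))
        p[f"{prefix}_q"] = ad.Tensor(rng.uniform(-k, k, size=(attn_dim, 1)))

    gru("gru1f", d); gru("gru1b", d); attn("att1", 2 * H)
    gru("gru2f", 2 * H); gru("gru2b", 2 * H); attn("att2", 2 * H)
    d3 = 2 * H + 2 * n_period_numeric
    gru("gru3f", d3); gru("gru3b", d3); attn("att3", 2 * H)
    fin = 2 * H + 2 * n_onsite
    k = np.sqrt(6.0 / (fin + ffn_dim))
    p["ffn_w1"] = ad.Tensor(rng.uniform(-k, k, size=(fin, ffn_dim)))
    p["ffn_b1"] = ad.Tensor(np.zeros(ffn_dim))
    k = np.sqrt(6.0 / (ffn_dim + 2 * N_LABELS))
    p["ffn_w2"] = ad.Tensor(rng.uniform(-k, k, size=(ffn_dim, 2 * N_LABELS)))
    p["ffn_b2"] = ad.Tensor(np.zeros(2 * N_LABELS))
    return p


# --------------------------------------------------------------------------
# Building blocks
# --------------------------------------------------------------------------


def bigru(x: ad.Tensor, mask: np.ndarray, params: dict, prefix: str) -> ad.Tensor:
    """Bidirectional GRU: forward and backward passes concatenated, (B,T,2H)."""
    hf = ad.gru_layer(x, mask, params[f"{prefix}f_wx"], params[f"{prefix}f_wh"],
                      params[f"{prefix}f_b"], reverse=False)
    hb = ad.gru_layer(x, mask, params[f"{prefix}b_wx"], params[f"{prefix}b_wh"],
                      params[f"{prefix}b_b"], reverse=True)
    return ad.concat([hf, hb], axis=-1)


def attention_pool_t(h: ad.Tensor, mask: np.ndarray, params: dict,
                     prefix: str) -> tuple[ad.Tensor, ad.Tensor]:
    """tanh-projection + learned-query softmax attention over axis 1.

    u_t = tanh(W h_t + b); a = softmax(<u_t, q>) over valid t;
    s = sum_t a_t h_t.  Returns (a, s).
    """
    B, T, _ = h.data.shape
    u = ad.tanh(ad.add(ad.matmul(h, params[f"{prefix}_w"]), params[f"{prefix}_b"]))
    logits = ad.reshape(ad.matmul(u, params[f"{prefix}_q"]), (B, T))
    a = ad.masked_softmax(logits, mask, axis=1)
    s = ad.sum_(ad.mul(ad.reshape(a, (B, T, 1)), h), axis=1)
    return a, s


@dataclass
class AttentionResult:
    weights: np.ndarray
    pooled: np.ndarray


def attention_pool(hidden: np.ndarray, params: dict, prefix: str = "att1") -> AttentionResult:
    """Functional single-sequence attention pool over (T, D) hidden states."""
    h = np.asarray(hidden, dtype=float)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("attention_pool needs a non-empty (T, D) matrix")
    a, s = attention_pool_t(ad.Tensor(h[None], requires_grad=False),
                            np.ones((1, h.shape[0])), params, prefix)
    return AttentionResult(weights=a.data[0], pooled=s.data[0])


def encode_sequence(inputs: np.ndarray, params: dict, prefix: str = "gru1") -> np.ndarray:
    """Functional biGRU encoding of one (T, D) sequence -> (T, 2H)."""
    x = np.asarray(inputs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("encode_sequence needs a non-empty (T, D) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    out = bigru(ad.Tensor(x[None], requires_grad=False), np.ones((1, x.shape[0])),
                params, prefix)
    return out.data[0]


# --------------------------------------------------------------------------
# Batch packing
# --------------------------------------------------------------------------


@dataclass
class _PackedVisit:
    tokens: np.ndarray     # (M, C, L_i) int, truncated to max_events_per_cell
    lengths: np.ndarray    # (M, C)
    pnum: np.ndarray       # (M, 2P) scaled values ++ observed indicators
    onsite: np.ndarray     # (2Q,)
    y: np.ndarray | None   # (4,)
    visit_id: str


def _scale(values, mask, mean, std):
    return np.where(mask > 0, (values - mean) / std, 0.0)


class _Scaler:
    """Per-variable standardisation statistics from observed entries."""

    def __init__(self, bundles):
        pv = np.concatenate([b.period_numeric.reshape(-1, b.period_numeric.shape[1])
                             for b in bundles])
        pm = np.concatenate([b.period_mask.reshape(-1, b.period_mask.shape[1])
                             for b in bundles])
        self.p_mean, self.p_std = self._stats(pv, pm)
        ov = np.stack([b.onsite_numeric for b in bundles])
        om = np.stack([b.onsite_mask for b in bundles])
        self.o_mean, self.o_std = self._stats(ov, om)

    @staticmethod
    def _stats(values, mask):
        cnt = np.maximum(mask.sum(axis=0), 1.0)
        mean = (values * mask).sum(axis=0) / cnt
        var = ((values - mean) ** 2 * mask).sum(axis=0) / cnt
        return mean, np.maximum(np.sqrt(var), 1e-6)


def pack_visit(bundle: VisitTensorBundle, scaler: _Scaler, cap: int) -> _PackedVisit:
    M = bundle.n_periods
    lengths = np.array([[min(len(cell), cap) for cell in row] for row in bundle.tokens])
    L = max(1, int(lengths.max()) if lengths.size else 1)
    tok = np.zeros((M, N_CONTEXTS, L), dtype=np.int64)
    for pidx, row in enumerate(bundle.tokens):
        for cidx, cell in enumerate(row):
            kept = cell[-cap:] if len(cell) > cap else cell   # most recent events
            tok[pidx, cidx, :len(kept)] = kept
    pnum = np.concatenate(
        [_scale(bundle.period_numeric, bundle.period_mask, scaler.p_mean, scaler.p_std),
         bundle.period_mask], axis=1)
    onsite = np.concatenate(
        [_scale(bundle.onsite_numeric, bundle.onsite_mask, scaler.o_mean, scaler.o_std),
         bundle.onsite_mask])
    y = bundle.labels.to_array() if bundle.labels is not None else None
    return _PackedVisit(tok, lengths, pnum, onsite, y, bundle.visit_id)


def _collate(packed: list[_PackedVisit]):
    B = len(packed)
    M, C = packed[0].lengths.shape
    L = max(p.tokens.shape[2] for p in packed)
    tok = np.zeros((B, M, C, L), dtype=np.int64)
    lens = np.zeros((B, M, C), dtype=np.int64)
    for i, p in enumerate(packed):
        tok[i, :, :, :p.tokens.shape[2]] = p.tokens
        lens[i] = p.lengths
    tmask = (np.arange(L)[None, None, None, :] < lens[..., None]).astype(float)
    cell_mask = (lens > 0).astype(float)
    pnum = np.stack([p.pnum for p in packed])
    onsite = np.stack([p.onsite for p in packed])
    y = np.stack([p.y for p in packed]) if packed[0].y is not None else None
    return tok, tmask, cell_mask, pnum, onsite, y


# --------------------------------------------------------------------------
# Forward pass
# --------------------------------------------------------------------------


def forward(params: dict, tok, tmask, cell_mask, pnum, onsite,
            capture: bool = False):
    """Full hierarchical forward pass on a collated batch.

    Returns (e_pos, e_neg) evidence Tensors of shape (B, 4) and, when
    ``capture`` is set, a trace dict with every attention group, pooled
    vector and hidden-state tensor (as numpy arrays).
    """
    B, M, C, L = tok.shape
    flat_tok = tok.reshape(-1, L)
    m1 = tmask.reshape(-1, L)

    x1 = ad.embedding(params["embed"], flat_tok)             # (BMC, L, d)
    h1 = bigru(x1, m1, params, "gru1")                       # (BMC, L, 2H)
    a1, s1 = attention_pool_t(h1, m1, params, "att1")        # (BMC, L), (BMC, 2H)

    ne = cell_mask.reshape(-1, 1)
    ctx_idx = np.tile(np.arange(C), B * M)
    empty = ad.embedding(params["empty_ctx"], ctx_idx)       # (BMC, 2H)
    cell = ad.add(ad.mul(s1, ne), ad.mul(empty, 1.0 - ne))

    twoH = cell.data.shape[1]
    x2 = ad.reshape(cell, (B * M, C, twoH))
    m2 = np.ones((B * M, C))
    h2 = bigru(x2, m2, params, "gru2")
    a2, s2 = attention_pool_t(h2, m2, params, "att2")        # (BM, C), (BM, 2H)

    period = ad.concat([s2, ad.Tensor(pnum.reshape(B * M, -1), requires_grad=False)],
                       axis=1)
    x3 = ad.reshape(period, (B, M, period.data.shape[1]))
    m3 = np.ones((B, M))
    h3 = bigru(x3, m3, params, "gru3")
    a3, s3 = attention_pool_t(h3, m3, params, "att3")        # (B, M), (B, 2H)

    patient = ad.concat([s3, ad.Tensor(onsite, requires_grad=False)], axis=1)
    f1 = ad.tanh(ad.add(ad.matmul(patient, params["ffn_w1"]), params["ffn_b1"]))
    ev = ad.softplus(ad.add(ad.matmul(f1, params["ffn_w2"]), params["ffn_b2"]))
    e_pos = ev[:, :N_LABELS]
    e_neg = ev[:, N_LABELS:]

    trace = None
    if capture:
        trace = {
            "event_attn": a1.data.reshape(B, M, C, L),
            "context_attn": a2.data.reshape(B, M, C),
            "period_attn": a3.data,
            "tokens": tok, "token_mask": tmask, "cell_mask": cell_mask,
            "event_hidden": h1.data.reshape(B, M, C, L, twoH),
            "event_pooled": s1.data.reshape(B, M, C, twoH),
            "context_hidden": h2.data.reshape(B, M, C, twoH),
            "context_pooled": s2.data.reshape(B, M, twoH),
            "period_hidden": h3.data,
            "period_pooled": s3.data,
        }
    return e_pos, e_neg, trace


# --------------------------------------------------------------------------
# Evidential loss
# --------------------------------------------------------------------------


def evidential_loss_t(e_pos: ad.Tensor, e_neg: ad.Tensor, y: np.ndarray,
                      lam: float) -> ad.Tensor:
    """Scalar loss Tensor: mean over the batch of the per-label sum."""
    if lam < 0 or lam > 1:
        raise ValueError("annealing coefficient must lie in [0, 1]")
    alpha = ad.add(e_pos, 1.0)
    beta = ad.add(e_neg, 1.0)
    S = ad.add(alpha, beta)
    p = ad.div(alpha, S)
    err = ad.square(ad.add(ad.mul(p, -1.0), y))
    var = ad.div(ad.mul(p, ad.add(ad.mul(p, -1.0), 1.0)), ad.add(S, 1.0))
    loss = ad.add(err, var)
    if lam > 0:
        alpha_t = ad.add(ad.mul(e_pos, 1.0 - y), 1.0)
        beta_t = ad.add(ad.mul(e_neg, y), 1.0)
        loss = ad.add(loss, ad.mul(ad.kl_beta_uniform(alpha_t, beta_t), lam))
    return ad.mean(ad.sum_(loss, axis=1))


def evidential_loss(e_pos, e_neg, y, lam: float = 0.0) -> float:
    """Functional evidential loss on numpy evidence arrays (summed over
    labels, averaged over rows)."""
    e_pos = np.atleast_2d(np.asarray(e_pos, dtype=float))
    e_neg = np.atleast_2d(np.asarray(e_neg, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if np.any(e_pos < 0) or np.any(e_neg < 0):
        raise ValueError("evidence must be non-negative")
    return float(evidential_loss_t(ad.Tensor(e_pos, requires_grad=False),
                                   ad.Tensor(e_neg, requires_grad=False),
                                   y, lam).data)


# --------------------------------------------------------------------------
# Estimator
# --------------------------------------------------------------------------


class CareNetClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical attention network over visit bundles, multilabel
    evidential output.

    Parameters mirror the desk-scale defaults: 16-dimensional embeddings
    and hidden states, M periods come from the bundles themselves, 20
    epochs of Adam at batch size 32 with the KL annealing coefficient
    ramping linearly to 1 over ``kl_anneal_epochs`` epochs.

    Attributes (after fit)
    ----------------------
    params_ : dict of named parameter tensors.
    loss_curve_ : list of per-epoch mean training losses.
    vocab_size_ : embedding rows.
    """

    def __init__(self, embed_dim: int = 16, hidden: int = 16, attn_dim: int = 32,
                 ffn_dim: int = 32, max_events_per_cell: int = 32,
                 lr: float = 3e-3, batch_size: int = 32, n_epochs: int = 20,
                 kl_anneal_epochs: int = 10, clip_norm: float = 5.0,
                 init_embeddings: np.ndarray | None = None,
                 random_state: int | None = None):
        self.embed_dim = embed_dim
        self.hidden = hidden
        self.attn_dim = attn_dim
        self.ffn_dim = ffn_dim
        self.max_events_per_cell = max_events_per_cell
        self.lr = lr
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.kl_anneal_epochs = kl_anneal_epochs
        self.clip_norm = clip_norm
        self.init_embeddings = init_embeddings
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, bundles: list[VisitTensorBundle], y=None,
            vocab_size: int | None = None):
        if not bundles:
            raise ValueError("no training bundles")
        ys = y if y is not None else np.stack([b.labels.to_array() for b in bundles])
        if (ys.sum(axis=0) > 0).sum() < 2:
            raise ValueError("training data must contain at least two labels")

        if vocab_size is None:
            if self.init_embeddings is not None:
                vocab_size = self.init_embeddings.shape[0]
            else:
                vocab_size = 1 + max((max((max(c) for c in row if c), default=0)
                                      for b in bundles for row in b.tokens), default=0)
        self.vocab_size_ = int(vocab_size)
        self.scaler_ = _Scaler(bundles)
        packed = [pack_visit(b, self.scaler_, self.max_events_per_cell)
                  for b in bundles]
        for p, yy in zip(packed, ys):
            p.y = np.asarray(yy, dtype=float)

        seeds = np.random.SeedSequence(self.random_state).spawn(2)
        init_rng = np.random.default_rng(seeds[0])
        shuffle_rng = np.random.default_rng(seeds[1])
        self.params_ = init_params(
            self.vocab_size_, self.embed_dim, self.hidden, self.attn_dim,
            n_period_numeric=bundles[0].period_numeric.shape[1],
            n_onsite=bundles[0].onsite_numeric.shape[0],
            ffn_dim=self.ffn_dim, rng=init_rng,
            init_embeddings=self.init_embeddings)
        opt = ad.Adam(self.params_, lr=self.lr)

        n = len(packed)
        self.loss_curve_ = []
        for epoch in range(self.n_epochs):
            lam = min(1.0, epoch / self.kl_anneal_epochs) if self.kl_anneal_epochs else 1.0
            order = shuffle_rng.permutation(n)
            total, nb = 0.0, 0
            for lo in range(0, n, self.batch_size):
                batch = [packed[i] for i in order[lo:lo + self.batch_size]]
                tok, tmask, cmask, pnum, onsite, yb = _collate(batch)
                e_pos, e_neg, _ = forward(self.params_, tok, tmask, cmask, pnum, onsite)
                loss = evidential_loss_t(e_pos, e_neg, yb, lam)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged (loss NaN) at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.clip_global_norm(self.clip_norm)
                opt.step()
                total += float(loss.data)
                nb += 1
            self.loss_curve_.append(total / nb)
        return self

    # -- inference ---------------------------------------------------------

    def _forward_bundles(self, bundles, capture=False, batch=64):
        packed = [pack_visit(b, self.scaler_, self.max_events_per_cell)
                  for b in bundles]
        e_pos_all, e_neg_all, traces = [], [], []
        for lo in range(0, len(packed), batch):
            chunk = packed[lo:lo + batch]
            tok, tmask, cmask, pnum, onsite, _ = _collate(chunk)
            e_pos, e_neg, trace = forward(self.params_, tok, tmask, cmask, pnum,
                                          onsite, capture=capture)
            e_pos_all.append(e_pos.data)
            e_neg_all.append(e_neg.data)
            if capture:
                for i, p in enumerate(chunk):
                    traces.append(HierarchyState(
                        event_attn=trace["event_attn"][i],
                        context_attn=trace["context_attn"][i],
                        period_attn=trace["period_attn"][i],
                        tokens=trace["tokens"][i],
                        token_mask=trace["token_mask"][i],
                        cell_mask=trace["cell_mask"][i],
                        visit_id=p.visit_id))
        return (np.concatenate(e_pos_all), np.concatenate(e_neg_all), traces)

    def predict_evidential(self, bundles) -> EvidentialOutput:
        e_pos, e_neg, _ = self._forward_bundles(bundles)
        return EvidentialOutput(e_pos=e_pos, e_neg=e_neg)

    def predict_proba(self, bundles) -> np.ndarray:
        """(n, 4) expected label probabilities p = alpha/(alpha+beta)."""
        return self.predict_evidential(bundles).prob

    def predict(self, bundles) -> np.ndarray:
        return self.predict_proba(bundles) >= 0.5

    def explain(self, bundles) -> list[HierarchyState]:
        """Capture the attention hierarchy for each visit."""
        _, _, traces = self._forward_bundles(bundles, capture=True)
        return traces

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {k: t.data for k, t in self.params_.items()}
        arrays["__scaler_p_mean"] = self.scaler_.p_mean
        arrays["__scaler_p_std"] = self.scaler_.p_std
        arrays["__scaler_o_mean"] = self.scaler_.o_mean
        arrays["__scaler_o_std"] = self.scaler_.o_std
        np.savez(path, **arrays,
                 __config=np.frombuffer(json.dumps(self.get_params(deep=False),
                                                   default=lambda o: None).encode(),
                                        dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "CareNetClassifier":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config"]).decode())
        cfg.pop("init_embeddings", None)
        est = cls(**cfg)
        est.params_ = {k: ad.Tensor(data[k]) for k in data.files
                       if not k.startswith("__")}
        sc = _Scaler.__new__(_Scaler)
        sc.p_mean, sc.p_std = data["__scaler_p_mean"], data["__scaler_p_std"]
        sc.o_mean, sc.o_std = data["__scaler_o_mean"], data["__scaler_o_std"]
        est.scaler_ = sc
        est.vocab_size_ = est.params_["embed"].data.shape[0]
        return est
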