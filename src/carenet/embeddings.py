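"""Skip-gram pretraining of event-code embeddings.

Event codes are treated like words: one "document" per patient — the
patient's full chronological event sequence — and skip-gram with negative
sampling learns a vector per code such that codes occurring in similar
neighbourhoods end up close.  The resulting table initialises the event
encoder of the network and is fine-tuned end to end afterwards.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .ehr import EMPTY_ID, Vocabulary


def build_corpus(events, vocab: Vocabulary) -> list[np.ndarray]:
    """One token-id sequence per patient, chronological (ties broken by
    code string), over the whole observation window."""
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = pd.DataFrame({
            "patient_id": [e.patient_id for e in events],
            "event_time": [e.event_time for e in events],
            "code": [e.code for e in events],
        })
    if df.empty:
        return []
    df = df.sort_values(["patient_id", "event_time", "code"], kind="mergesort")
    ids = df["code"].map(vocab.encode).to_numpy(dtype=np.int64)
    bounds = np.flatnonzero(np.r_[True, df["patient_id"].to_numpy()[1:]
                                  != df["patient_id"].to_numpy()[:-1]])
    return [seq for seq in np.split(ids, bounds[1:])]


class SkipGramEmbeddings(BaseEstimator):
    """Skip-gram-with-negative-sampling embeddings of event codes.

    Parameters
    ----------
    vector_size : embedding dimensionality d.
    window : max distance between centre and context token.
    negative : negative samples per positive pair.
    epochs : passes over the pair list.
    lr : learning rate on the mean minibatch gradient.
    batch_size : pairs per vectorised SGD step.
    max_pairs : optional cap on pairs per epoch (subsampled with the rng).
    random_state : seed; fixed seed + single thread => identical tables.

    Attributes
    ----------
    embeddings_ : (V, d) input-vector table; row 0 (the EMPTY token) stays
        all-zero, codes never seen in the corpus keep their N(0, 0.1) init.
    """

    def __init__(self, vector_size: int = 16, window: int = 5, negative: int = 5,
                 epochs: int = 2, lr: float = 20.0, batch_size: int = 8192,
                 max_pairs: int | None = None, random_state: int | None = None):
        self.vector_size = vector_size
        self.window = window
        self.negative = negative
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.max_pairs = max_pairs
        self.random_state = random_state

    def fit(self, corpus: list[np.ndarray], vocab_size: int):
        if self.vector_size <= 0:
            raise ValueError("vector_size must be positive")
        if not corpus:
            raise ValueError("corpus is empty")
        rng = np.random.default_rng(self.random_state)
        d = self.vector_size
        W_in = rng.normal(0.0, 0.1, size=(vocab_size, d))
        W_out = np.zeros((vocab_size, d))
        W_in[EMPTY_ID] = 0.0

        centers, contexts = [], []
        for seq in corpus:
            for off in range(1, self.window + 1):
                if len(seq) > off:
                    centers.append(seq[:-off]); contexts.append(seq[off:])
                    centers.append(seq[off:]); contexts.append(seq[:-off])
        if not centers:
            # corpus of length-1 sequences only: nothing to train on
            self.embeddings_ = W_in
            return self
        centers = np.concatenate(centers)
        contexts = np.concatenate(contexts)

        counts = np.bincount(np.concatenate(corpus), minlength=vocab_size).astype(float)
        counts[EMPTY_ID] = 0.0
        noise = counts ** 0.75
        noise /= noise.sum()

        n_pairs = centers.size
        for _ in range(self.epochs):
            order = rng.permutation(n_pairs)
            if self.max_pairs is not None and n_pairs > self.max_pairs:
                order = order[:self.max_pairs]
            for lo in range(0, order.size, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                c, o = centers[idx], contexts[idx]
                # minibatch gradient of the mean pair loss: updates are
                # normalised by the batch size, so repeated codes within a
                # batch do not compound the step
                step = self.lr / idx.size
                v = W_in[c]                                   # (B, d)
                upos = W_out[o]
                gpos = expit((v * upos).sum(axis=1)) - 1.0    # (B,)
                neg = rng.choice(vocab_size, size=(idx.size, self.negative), p=noise)
                uneg = W_out[neg]                             # (B, K, d)
                gneg = expit(np.einsum("bd,bkd->bk", v, uneg))
                dv = gpos[:, None] * upos + np.einsum("bk,bkd->bd", gneg, uneg)
                np.add.at(W_out, o, -step * gpos[:, None] * v)
                np.add.at(W_out, neg.ravel(),
                          (-step * gneg[..., None] * v[:, None, :]).reshape(-1, d))
                np.add.at(W_in, c, -step * dv)
        W_in[EMPTY_ID] = 0.0
        if not np.all(np.isfinite(W_in)):
            raise FloatingPointError("non-finite embeddings after training")
        self.embeddings_ = W_in
        return self


def train_skipgram(corpus: list[np.ndarray], vocab_size: int, d: int = 16,
                   window: int = 5, negatives: int = 5, epochs: int = 2,
                   seed: int | None = None, **kw) -> np.ndarray:
    """Functional wrapper returning the (V, d) embedding table."""
    est = SkipGramEmbeddings(vector_size=d, window=window, negative=negatives,
                             epochs=epochs, random_state=seed, **kw)
    return est.fit(corpus, vocab_size).embeddings_


def write_embeddings(table: np.ndarray, vocab: Vocabulary, path) -> None:
    """Persist embeddings as TSV (token, then d floats) for inspection."""
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(table.shape[0]):
            vals = "\t".join(format(x, ".8g") for x in table[i])
            fh.write(f"{vocab.decode(i)}\t{vals}\n")


def load_embeddings_tsv(path) -> tuple[np.ndarray, Vocabulary]:
    """Load an embeddings TSV written by :func:`write_embeddings`,
    reconstructing the vocabulary from the row order (reserved rows first,
    then codes in id order)."""
    tokens, rows = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    vocab = Vocabulary(tokens[2:])
    return np.array(rows), vocab


def read_embeddings(path, vocab: Vocabulary) -> np.ndarray:
    rows = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows[parts[0]] = np.array([float(x) for x in parts[1:]])
    d = len(next(iter(rows.values())))
    out = np.zeros((len(rows), d))
    for i in range(len(rows)):
        out[i] = rows[vocab.decode(i)]
    return out
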