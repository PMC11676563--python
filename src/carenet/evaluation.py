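"""Evaluation protocol: micro AUROC, 10x10 CV/bootstrap matrix, sensitivity
at a specificity floor, and subgroup summaries.

Micro averaging pools all (visit, label) score–truth pairs across the four
labels before computing the AUROC, so every visit carries the same weight
regardless of which labels it has.  The headline protocol is 10-fold
cross-validation with, per fold, 10 evaluations on a random 90% subsample
of the held-out fold, yielding a 10x10 AUROC matrix summarised by its
median and 2.5–97.5 percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass
class ScoreFrame:
    """Per-visit label scores, truths, and subgroup attributes."""

    scores: np.ndarray                 # (n, 4) in (0, 1) or any ranking scale
    labels: np.ndarray                 # (n, 4) boolean
    attrs: pd.DataFrame | None = None  # age, sex, history flags, ...


def micro_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC over the pooled (visit, label) pairs: the probability that a
    random positive pair outranks a random negative one, ties counting 1/2."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("micro AUROC needs at least one positive and one negative")
    return float(roc_auc_score(y, s))


def sens_at_spec(scores: np.ndarray, labels: np.ndarray,
                 floor: float = 0.75) -> tuple[float, float, float]:
    """Operating point with maximum sensitivity among thresholds whose
    specificity exceeds ``floor``.

    All observed score values are scanned as thresholds (prediction is
    positive when score >= threshold); ties on sensitivity resolve to the
    lowest threshold.  If no threshold clears the floor, (0, 1, +inf) is
    returned with a warning.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=bool).ravel()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    ss, yy = s[order], y[order]
    # candidate thresholds: each distinct score (predict positive if >= t)
    distinct = np.r_[True, ss[1:] != ss[:-1]]
    tp = np.cumsum(yy)
    fp = np.cumsum(~yy)
    last = np.flatnonzero(np.r_[distinct[1:], True])  # last index of each tie block
    sens = tp[last] / n_pos
    spec = 1.0 - fp[last] / n_neg
    thr = ss[last]
    ok = spec > floor
    if not ok.any():
        warnings.warn(f"no operating point with specificity > {floor}")
        return 0.0, 1.0, float("inf")
    best_sens = sens[ok].max()
    cand = ok & (sens == best_sens)
    i = np.flatnonzero(cand)[-1]   # lowest threshold among ties (sorted desc)
    return float(sens[i]), float(spec[i]), float(thr[i])


def summarize(matrix: np.ndarray) -> tuple[float, float, float]:
    """(median, 2.5 percentile, 97.5 percentile) over non-NaN entries,
    linear interpolation."""
    vals = np.asarray(matrix, dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("all entries are NaN")
    lo, med, hi = np.percentile(vals, [2.5, 50.0, 97.5], method="linear")
    return float(med), float(lo), float(hi)


def _label_pattern_strata(y: np.ndarray, folds: int) -> np.ndarray:
    """Stratify by the full label pattern; patterns too rare to appear in
    every fold are pooled into one stratum."""
    pat = np.array(["".join(str(int(v)) for v in row) for row in np.asarray(y, dtype=int)])
    vals, counts = np.unique(pat, return_counts=True)
    rare = set(vals[counts < folds])
    if rare:
        pat = np.array([p if p not in rare else "__rare__" for p in pat])
    return pat


def cv_bootstrap_with_scores(X, y: np.ndarray, model_factory, folds: int = 10,
                             boots: int = 10, frac: float = 0.9,
                             seed: int | None = None,
                             replace: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """As :func:`cv_bootstrap`, also returning the out-of-fold score matrix
    (every visit scored by the model that did not see it)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    strata = _label_pattern_strata(y, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    matrix = np.full((folds, boots), np.nan)
    oof = np.full((n, y.shape[1]), np.nan)
    is_list = isinstance(X, (list, tuple))

    for f, (tr, te) in enumerate(skf.split(np.zeros(n), strata)):
        model = model_factory()
        Xtr = [X[i] for i in tr] if is_list else X[tr]
        Xte = [X[i] for i in te] if is_list else X[te]
        model.fit(Xtr, y[tr])
        scores = np.asarray(model.predict_proba(Xte))
        oof[te] = scores
        yte = y[te]
        m = max(1, int(round(frac * len(te))))
        for b in range(boots):
            idx = rng.choice(len(te), size=m, replace=replace)
            ys = yte[idx]
            if ys.sum() == 0 or ys.sum() == ys.size:
                warnings.warn(f"fold {f} bootstrap {b}: degenerate labels, NaN recorded")
                continue
            matrix[f, b] = micro_auroc(scores[idx], ys)
    return matrix, oof


def cv_bootstrap(X, y: np.ndarray, model_factory, folds: int = 10,
                 boots: int = 10, frac: float = 0.9,
                 seed: int | None = None, replace: bool = False) -> np.ndarray:
    """The headline protocol: ``folds``-fold CV stratified by label
    pattern; per fold, ``boots`` evaluations each on ``frac`` of the
    held-out fold (without replacement by default, with replacement if
    ``replace``).  Returns a (folds, boots) matrix of micro AUROCs;
    degenerate bootstrap samples record NaN with a warning.

    ``X`` is whatever the estimators from ``model_factory`` accept (a
    feature matrix or a list of visit bundles); ``model_factory()`` must
    return an object with fit(X, y) and predict_proba(X) -> (n, 4).
    """
    matrix, _ = cv_bootstrap_with_scores(X, y, model_factory, folds=folds,
                                         boots=boots, frac=frac, seed=seed,
                                         replace=replace)
    return matrix


def subgroup_report(frame: ScoreFrame, splits: dict[str, np.ndarray],
                    n_boot: int = 100, seed: int | None = None) -> pd.DataFrame:
    """Micro AUROC per subgroup with bootstrap 2.5–97.5 percentiles.

    ``splits`` maps a group name to a boolean visit mask.  Empty groups
    yield a NaN row.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, mask in splits.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            rows.append({"group": name, "n": 0, "auroc": np.nan,
                         "p2.5": np.nan, "p97.5": np.nan})
            continue
        s, y = frame.scores[mask], frame.labels[mask]
        point = micro_auroc(s, y)
        vals = []
        for _ in range(n_boot):
            idx = rng.choice(mask.sum(), size=mask.sum(), replace=True)
            ys = y[idx]
            if 0 < ys.sum() < ys.size:
                vals.append(micro_auroc(s[idx], ys))
        med, lo, hi = summarize(np.array(vals)) if vals else (np.nan, np.nan, np.nan)
        rows.append({"group": name, "n": int(mask.sum()), "auroc": point,
                     "p2.5": lo, "p97.5": hi})
    return pd.DataFrame(rows)


def roc_points(scores: np.ndarray, labels: np.ndarray,
               label_names=("ahf", "ecopd", "pneumonia", "other")) -> pd.DataFrame:
    """Per-label ROC curve points (false positive rate, sensitivity,
    threshold) in long format, ready for CSV export."""
    from sklearn.metrics import roc_curve

    frames = []
    for j, name in enumerate(label_names):
        fpr, tpr, thr = roc_curve(np.asarray(labels)[:, j],
                                  np.asarray(scores)[:, j])
        frames.append(pd.DataFrame({"label": name, "fpr": fpr,
                                    "sensitivity": tpr, "threshold": thr}))
    return pd.concat(frames, ignore_index=True)


def evaluation_report(matrix: np.ndarray, scores: np.ndarray | None = None,
                      labels: np.ndarray | None = None,
                      label_names=("ahf", "ecopd", "pneumonia", "other"),
                      spec_floor: float = 0.75) -> dict:
    """JSON-ready report: the AUROC matrix, its summary, and (optionally)
    the per-label sensitivity/specificity table at the specificity floor."""
    med, lo, hi = summarize(matrix)
    report = {
        "auroc_matrix": np.asarray(matrix).tolist(),
        "micro_auroc": {"median": med, "p2.5": lo, "p97.5": hi},
    }
    if scores is not None and labels is not None:
        per_label = {}
        for j, name in enumerate(label_names):
            sens, spec, thr = sens_at_spec(scores[:, j], labels[:, j], spec_floor)
            per_label[name] = {"sensitivity": sens, "specificity": spec,
                               "threshold": thr}
        report["sens_at_spec"] = per_label
    return report
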