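"""Expert-feature comparison model: nine clinician-chosen variables,
iterative random-forest imputation, gradient-boosted trees per label.

The nine features are age, sex, a diagnosis of heart failure / COPD /
pneumonia anywhere in the system within five years before the index visit,
a diagnosis of AHF / eCOPD / pneumonia at an ED within one year, and the
triage temperature (the only feature with missing values).  The baseline
is scored through exactly the same evaluation code path as the network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor

from .ehr import (Context, IndexVisit, is_ahf_code, is_ecopd_code,
                  is_pneumonia_code)

FEATURE_NAMES = ["age", "sex", "hx_hf_5y", "hx_copd_5y", "hx_pneumonia_5y",
                 "ed_ahf_1y", "ed_ecopd_1y", "ed_pneumonia_1y", "temperature"]

_YEAR_S = 365.25 * 86400.0


def _dx_part(code: str) -> str | None:
    """ICD-10 part of a coded diagnosis event ('DX:I50.9' -> 'I50.9')."""
    if code.startswith("DX:"):
        return code[3:]
    return None


def extract_features(events, visit: IndexVisit) -> np.ndarray:
    """The nine expert features for one visit (temperature may be NaN).

    History flags use ICD-10 prefix matching on diagnosis events: the
    five-year flags count any care context, the one-year flags only ED
    events.  Temperature is the onsite triage measurement.
    """
    if isinstance(events, pd.DataFrame):
        it = ((row.event_time, row.context, row.code)
              for row in events.itertuples(index=False))
    else:
        it = ((e.event_time, e.context, e.code) for e in events)
    hx = np.zeros(3)
    ed1 = np.zeros(3)
    for t, ctx, code in it:
        part = _dx_part(code)
        if part is None:
            continue
        try:
            flags = (is_ahf_code(part), is_ecopd_code(part), is_pneumonia_code(part))
        except Exception:
            continue
        if not any(flags):
            continue
        age_s = (visit.index_time - pd.Timestamp(t)).total_seconds()
        if age_s <= 0:
            continue
        is_ed = (ctx == Context.ED) or (ctx == Context.ED.name)
        for j in range(3):
            if flags[j]:
                if age_s <= 5 * _YEAR_S:
                    hx[j] = 1.0
                if is_ed and age_s <= _YEAR_S:
                    ed1[j] = 1.0
    names = visit.onsite_names
    def onsite(name, default=np.nan):
        if name in names:
            i = names.index(name)
            return visit.onsite[i] if visit.onsite_mask[i] > 0 else np.nan
        return default
    age = onsite("age")
    sex = onsite("sex")
    temp = onsite("temp", onsite("temperature"))
    return np.array([age, sex, hx[0], hx[1], hx[2], ed1[0], ed1[1], ed1[2], temp])


def extract_feature_table(events_df: pd.DataFrame,
                          visits: list[IndexVisit]) -> pd.DataFrame:
    """Feature rows for a whole cohort (vectorised grouping by visit)."""
    by_visit = dict(tuple(events_df.groupby("visit_id"))) if not events_df.empty else {}
    empty = events_df.iloc[0:0]
    rows = [extract_features(by_visit.get(v.visit_id, empty), v) for v in visits]
    return pd.DataFrame(rows, columns=FEATURE_NAMES,
                        index=[v.visit_id for v in visits])


class MissForestImputer(BaseEstimator, TransformerMixin):
    """Iterative random-forest imputation of missing numeric entries.

    Starting from mean fill, each incomplete column (in order of ascending
    missingness) is regressed on the others with a random forest and its
    missing entries replaced by predictions, repeating until the total
    change in imputed values increases or ``max_iter`` is reached.
    """

    def __init__(self, max_iter: int = 10, n_estimators: int = 50,
                 random_state: int | None = None):
        self.max_iter = max_iter
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit_transform(self, X, y=None):
        df = pd.DataFrame(X).astype(float)
        miss = df.isna()
        if miss.all(axis=0).any():
            bad = list(df.columns[miss.all(axis=0)])
            raise ValueError(f"column(s) entirely missing: {bad}")
        self.n_iter_ = 0
        if not miss.any().any():
            return df.to_numpy() if not isinstance(X, pd.DataFrame) else df
        filled = df.fillna(df.mean())
        cols = [c for c in df.columns if miss[c].any()]
        cols.sort(key=lambda c: miss[c].sum())
        prev_delta = np.inf
        best = filled.copy()
        rng = np.random.default_rng(self.random_state)
        for it in range(self.max_iter):
            old = filled.copy()
            for c in cols:
                mask = miss[c].to_numpy()
                others = [o for o in df.columns if o != c]
                rf = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    random_state=int(rng.integers(2 ** 31)))
                rf.fit(filled.loc[~mask, others], filled.loc[~mask, c])
                filled.loc[mask, c] = rf.predict(filled.loc[mask, others])
            num = sum(((filled[c] - old[c]) ** 2)[miss[c]].sum() for c in cols)
            den = sum((filled[c] ** 2)[miss[c]].sum() for c in cols) or 1.0
            delta = num / den
            self.n_iter_ = it + 1
            if delta >= prev_delta:
                filled = best  # change increased: keep previous iterate
                break
            prev_delta = delta
            best = filled.copy()
        return filled if isinstance(X, pd.DataFrame) else filled.to_numpy()

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def impute_missforest(table, max_iter: int = 10, seed: int | None = None,
                      n_estimators: int = 50):
    """Functional wrapper over :class:`MissForestImputer`."""
    return MissForestImputer(max_iter=max_iter, n_estimators=n_estimators,
                             random_state=seed).fit_transform(table)


class ExpertFeatureBaseline(BaseEstimator):
    """Four one-vs-rest gradient-boosted tree scorers over the nine expert
    features (lightgbm backend, depth 6, 200 rounds)."""

    def __init__(self, n_estimators: int = 200, max_depth: int = 6,
                 learning_rate: float = 0.1, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        # lightgbm tracks feature names; canonical columns keep fit and
        # predict consistent whether callers pass arrays or DataFrames
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])

    def fit(self, X, y):
        from lightgbm import LGBMClassifier

        X = self._frame(X)
        y = np.asarray(y, dtype=int)
        self.models_ = []
        for j in range(y.shape[1]):
            col = y[:, j]
            if col.min() == col.max():
                raise ValueError(f"label column {j} has a single class")
            m = LGBMClassifier(n_estimators=self.n_estimators,
                               max_depth=self.max_depth,
                               learning_rate=self.learning_rate,
                               random_state=self.random_state,
                               deterministic=True, n_jobs=1, verbose=-1)
            m.fit(X, col)
            self.models_.append(m)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._frame(X)
        return np.column_stack([m.predict_proba(X)[:, 1] for m in self.models_])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= 0.5


def train_baseline(features, labels, seed: int | None = None,
                   **kw) -> ExpertFeatureBaseline:
    return ExpertFeatureBaseline(random_state=seed, **kw).fit(features, labels)
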