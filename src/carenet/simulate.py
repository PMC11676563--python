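"""Synthetic ED-dyspnoea cohort generator with known ground truth.

The generator emulates the statistical structure the classifier assumes:
each visit carries a latent triple of disease indicators (AHF, eCOPD,
pneumonia) drawn independently at prevalences (0.155, 0.140, 0.133); given
the latent state, a LogNormal number of coded events (median 352, IQR
134–838 over a one-year window) is emitted from a categorical distribution
in which each active label multiplies the rate of its k planted signal
codes by e^gamma.  Signal codes have "home" care contexts so that
context-level attention is testable; vital-sign observations are
label-dependent Gaussians; recorded main diagnoses (and hence labels) can
be flipped at a configurable noise rate to emulate un-adjudicated charts.

Because the generative model is fully known, the exact posterior
probability of every label given a visit's data is computable in closed
form (enumerating the 8 latent configurations); :func:`bayes_oracle_auc`
turns those posteriors into the AUROC ceiling no classifier can beat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .ehr import (CONTEXT_NAMES, Context, IndexVisit, map_icd10_to_labelset,
                  write_event_stream, write_index_visits)

DISEASES = ("ahf", "ecopd", "pneumonia")
ALL_LABELS = ("ahf", "ecopd", "pneumonia", "other")
MAIN_DX = {"ahf": "I50.9", "ecopd": "J44.1", "pneumonia": "J18.9"}
OTHER_DX = "R06.0"
HISTORY_DX = {"ahf": "DX:I50", "ecopd": "DX:J44", "pneumonia": "DX:J18"}
HOME_CONTEXT = {"ahf": Context.PRIMARY_CARE, "ecopd": Context.OTHERS,
                "pneumonia": Context.ED, "other": Context.OUTPATIENT_SPECIALIST}

# name -> (baseline mean, sd, (AHF, eCOPD, pneumonia) additive effects)
VITALS = {
    "TEMP": (37.0, 0.6, (0.0, 0.0, 1.2)),
    "HR": (82.0, 14.0, (8.0, 0.0, 0.0)),
    "RESP": (17.0, 4.0, (0.0, 4.0, 0.0)),
    "SBP": (135.0, 18.0, (0.0, 0.0, 0.0)),
    "SPO2": (96.0, 2.5, (-1.5, -2.0, -1.0)),
}
VITAL_CODES = [f"VITAL:{k}" for k in VITALS]

ONSITE_NAMES = ["age", "sex", "temp", "hr", "resp", "sbp", "spo2",
                "ambulance", "triage_priority", "arrival_hour", "ed_occupancy"]
_ONSITE_VITAL_SLICE = slice(2, 7)  # temp..spo2 align with VITALS order


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_visits: int = 2000
    vocab_size: int = 200
    signal_codes_per_label: int = 5
    gamma: float = 1.5                      # log rate ratio of signal codes
    prevalences: tuple = (0.155, 0.140, 0.133)
    events_median: float = 352.0
    events_iqr: tuple = (134.0, 838.0)
    context_probs: tuple = (0.28, 0.12, 0.14, 0.08, 0.05, 0.33)
    vital_events_mean: float = 6.0
    missing_rate: float = 0.02
    label_noise: float = 0.0                # 0.05 emulates pre-adjudication labels
    history_signal: float = 0.0             # P(prior qualifying dx | label active)
    history_background: float = 0.05        # same, label inactive
    window_weeks: int = 52
    home_context_prob: float = 0.7
    vital_effect_scale: float = 1.0         # 0 silences the vital-sign signal
    seed: int = 0

    def __post_init__(self):
        if not all(0.0 < p < 1.0 for p in self.prevalences):
            raise ValueError("prevalences must lie in (0, 1)")
        if self.signal_codes_per_label * 4 > self.vocab_size:
            raise ValueError("infeasible config: 4*k signal codes exceed vocabulary")

    @property
    def lognormal_mu(self) -> float:
        return float(np.log(self.events_median))

    @property
    def lognormal_sigma(self) -> float:
        lo, hi = self.events_iqr
        return float(np.log(hi / lo) / (2 * 0.6744897501960817))


@dataclass
class GroundTruth:
    signal_codes: dict            # label -> list of code strings
    signal_indices: dict          # label -> np.ndarray of code-universe indices
    gamma: float
    latent: np.ndarray            # (n, 3) bool latent disease indicators
    logits: np.ndarray            # (n, 4) exact posterior log-odds per label
    visit_ids: list

    def to_json(self) -> str:
        return json.dumps({
            "signal_codes": self.signal_codes,
            "gamma": self.gamma,
            "latent": self.latent.astype(int).tolist(),
            "logits": self.logits.tolist(),
            "visit_ids": list(self.visit_ids),
        }, indent=1)


@dataclass
class Cohort:
    events: pd.DataFrame
    visits: list
    truth: GroundTruth
    config: SimConfig

    def labels_array(self) -> np.ndarray:
        """Realised (n, 4) label matrix from the recorded main diagnoses."""
        return np.stack([map_icd10_to_labelset(v.main_dx_codes).to_array()
                         for v in self.visits]) if self.visits else np.zeros((0, 4))

    def write(self, outdir) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        write_event_stream(self.events, os.path.join(outdir, "events.tsv"))
        write_index_visits(self.visits, os.path.join(outdir, "visits.tsv"))
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            fh.write(self.truth.to_json())


def _code_universe(V: int) -> tuple[list[str], list[str]]:
    """Deterministic V-code universe with mixed prefixes; returns codes and
    the value_class string each carries (labs only)."""
    prefixes = ["RX:C", "LAB:B", "PROC:K", "COMPLAINT:S", "DX:Z"]
    suffixes = ["LOW", "NORMAL", "HIGH"]
    codes, vclasses = [], []
    for i in range(V):
        pfx = prefixes[i % len(prefixes)]
        if pfx.startswith("LAB"):
            sfx = suffixes[(i // len(prefixes)) % 3]
            codes.append(f"{pfx}{i:03d}:{sfx}")
            vclasses.append(sfx)
        else:
            codes.append(f"{pfx}{i:03d}")
            vclasses.append("")
    return codes, vclasses


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Draw one cohort; fixed seed reproduces it exactly."""
    rng = np.random.default_rng(cfg.seed)
    V = cfg.vocab_size
    k = cfg.signal_codes_per_label
    codes, vclasses = _code_universe(V)
    base_w = 1.0 / (np.arange(V) + 10.0)     # mildly Zipf-like background rates

    hi = min(150, V)
    sig_pool = rng.choice(np.arange(10, hi), size=4 * k, replace=False)
    signal_indices = {lab: np.sort(sig_pool[j * k:(j + 1) * k])
                      for j, lab in enumerate(ALL_LABELS)}
    signal_codes = {lab: [codes[i] for i in idx] for lab, idx in signal_indices.items()}
    is_signal = np.full(V, -1)
    for j, lab in enumerate(ALL_LABELS):
        is_signal[signal_indices[lab]] = j

    window_s = cfg.window_weeks * 7 * 86400.0
    pi = np.asarray(cfg.prevalences)
    ctx_p = np.asarray(cfg.context_probs, dtype=float)
    ctx_p = ctx_p / ctx_p.sum()
    n = cfg.n_visits

    latent = rng.random((n, 3)) < pi
    flips = rng.random((n, 3)) < cfg.label_noise
    realized = latent ^ flips
    n_events = np.maximum(1, np.round(rng.lognormal(
        cfg.lognormal_mu, cfg.lognormal_sigma, size=n))).astype(int)
    index_days = rng.integers(0, 365, size=n)
    index_secs = rng.integers(0, 86400, size=n)
    t0 = pd.Timestamp("2019-01-01")

    ev_pid, ev_vid, ev_time, ev_ctx, ev_code, ev_vc, ev_num = [], [], [], [], [], [], []
    visits: list[IndexVisit] = []
    # sufficient statistics for the oracle
    n_sig = np.zeros((n, 4))
    vital_sums = np.zeros((n, len(VITALS)))
    vital_sq = np.zeros((n, len(VITALS)))
    vital_cnt = np.zeros((n, len(VITALS)))
    hist_flags = np.zeros((n, 3), dtype=bool)

    vital_names = list(VITALS)
    vmeans = np.array([VITALS[v][0] for v in vital_names])
    vsds = np.array([VITALS[v][1] for v in vital_names])
    veff = cfg.vital_effect_scale * np.array([VITALS[v][2] for v in vital_names])  # (P, 3)

    for i in range(n):
        pid, vid = f"P{i:05d}", f"V{i:05d}"
        idx_time = t0 + pd.Timedelta(days=int(index_days[i]), seconds=int(index_secs[i]))
        z = latent[i]

        active = np.r_[z, not z.any()]          # "other" is the completion
        rate = base_w.copy()
        for j, lab in enumerate(ALL_LABELS):
            if active[j]:
                rate[signal_indices[lab]] *= np.exp(cfg.gamma)
        counts = rng.multinomial(n_events[i], rate / rate.sum())
        code_idx = np.repeat(np.arange(V), counts)
        m = code_idx.size
        for j, lab in enumerate(ALL_LABELS):
            n_sig[i, j] = counts[signal_indices[lab]].sum()

        ctx = rng.choice(6, size=m, p=ctx_p)
        sig_lab = is_signal[code_idx]
        home = sig_lab >= 0
        if home.any():
            use_home = rng.random(m) < cfg.home_context_prob
            sel = home & use_home
            homes = np.array([int(HOME_CONTEXT[ALL_LABELS[j]]) if j >= 0 else 0
                              for j in sig_lab[sel]])
            ctx[sel] = homes
        ages = rng.uniform(60.0, window_s, size=m)

        # vital-sign observations scattered over the window
        n_vit = rng.poisson(cfg.vital_events_mean)
        vit_var = rng.integers(0, len(vital_names), size=n_vit)
        vit_mu = vmeans[vit_var] + veff[vit_var] @ z.astype(float)
        vit_val = rng.normal(vit_mu, vsds[vit_var])
        vit_missing = rng.random(n_vit) < cfg.missing_rate
        vit_ages = rng.uniform(60.0, window_s, size=n_vit)
        vit_ctx = rng.choice(6, size=n_vit, p=ctx_p)
        for w, val, miss in zip(vit_var, vit_val, vit_missing):
            if not miss:
                vital_sums[i, w] += val
                vital_sq[i, w] += val * val
                vital_cnt[i, w] += 1

        # optional planted history diagnoses (the expert-feature pathway)
        hist_events = []
        if cfg.history_signal > 0:
            for j, lab in enumerate(DISEASES):
                p = cfg.history_signal if z[j] else cfg.history_background
                if rng.random() < p:
                    hist_flags[i, j] = True
                    hist_events.append((HISTORY_DX[lab],
                                        rng.uniform(60.0, window_s),
                                        rng.choice(6, p=ctx_p)))

        all_codes = ([codes[c] for c in code_idx]
                     + [vital_names[w] for w in vit_var]
                     + [h[0] for h in hist_events])
        n_tot = len(all_codes)
        ev_pid.extend([pid] * n_tot)
        ev_vid.extend([vid] * n_tot)
        age_all = np.concatenate([ages, vit_ages, np.array([h[1] for h in hist_events])]) \
            if n_tot else np.empty(0)
        ev_time.extend((idx_time - pd.to_timedelta(np.floor(age_all), unit="s")).tolist())
        ctx_all = np.concatenate([ctx, vit_ctx,
                                  np.array([h[2] for h in hist_events], dtype=int)]) \
            if n_tot else np.empty(0, dtype=int)
        ev_ctx.extend(CONTEXT_NAMES[c] for c in ctx_all)
        ev_code.extend([codes[c] for c in code_idx])
        ev_code.extend(f"VITAL:{vital_names[w]}" for w in vit_var)
        ev_code.extend(h[0] for h in hist_events)
        ev_vc.extend(vclasses[c] for c in code_idx)
        ev_vc.extend("NA" if miss else "" for miss in vit_missing)
        ev_vc.extend([""] * len(hist_events))
        ev_num.extend([np.nan] * m)
        ev_num.extend(np.nan if miss else round(float(val), 1)
                      for val, miss in zip(vit_val, vit_missing))
        ev_num.extend([np.nan] * len(hist_events))

        # onsite triage variables
        age_y = float(np.clip(np.round(rng.normal(75, 12)), 18, 100))
        sex = float(rng.random() < 0.52)
        triage_mu = vmeans + veff @ z.astype(float)
        triage = rng.normal(triage_mu, vsds)
        triage_miss = rng.random(len(vital_names)) < cfg.missing_rate
        for w in range(len(vital_names)):
            if not triage_miss[w]:
                vital_sums[i, w] += triage[w]
                vital_sq[i, w] += triage[w] ** 2
                vital_cnt[i, w] += 1
        onsite = np.concatenate([
            [age_y, sex], np.round(triage, 1),
            [float(rng.random() < 0.3), float(rng.integers(1, 6)),
             float(rng.integers(0, 24)), float(rng.poisson(20))]])
        mask = np.ones_like(onsite)
        mask[_ONSITE_VITAL_SLICE] = (~triage_miss).astype(float)
        onsite = np.where(mask > 0, onsite, 0.0)

        dx = [MAIN_DX[lab] for j, lab in enumerate(DISEASES) if realized[i, j]]
        if not dx:
            dx = [OTHER_DX]
        visits.append(IndexVisit(visit_id=vid, patient_id=pid, index_time=idx_time,
                                 onsite=onsite, onsite_mask=mask,
                                 onsite_names=list(ONSITE_NAMES), main_dx_codes=dx))

    events = pd.DataFrame({
        "patient_id": ev_pid, "visit_id": ev_vid,
        "event_time": pd.to_datetime(ev_time) if ev_time else pd.Series(dtype="datetime64[ns]"),
        "context": pd.Series(ev_ctx, dtype=str),
        "code": pd.Series(ev_code, dtype=str),
        "value_class": pd.Series(ev_vc, dtype=str),
        "numeric_value": pd.Series(ev_num, dtype=float),
    })

    logits = _posterior_logits(cfg, base_w, signal_indices, n_sig, n_events,
                               vital_sums, vital_sq, vital_cnt, hist_flags)
    truth = GroundTruth(signal_codes=signal_codes, signal_indices=signal_indices,
                        gamma=cfg.gamma, latent=latent, logits=logits,
                        visit_ids=[v.visit_id for v in visits])
    return Cohort(events=events, visits=visits, truth=truth, config=cfg)


def _posterior_logits(cfg, base_w, signal_indices, n_sig, n_events,
                      vital_sums, vital_sq, vital_cnt, hist_flags) -> np.ndarray:
    """Exact per-label posterior log-odds under the generative model,
    enumerating the 8 latent disease configurations."""
    n = n_sig.shape[0]
    if n == 0:
        return np.zeros((0, 4))
    pi = np.asarray(cfg.prevalences)
    W = np.array([base_w[signal_indices[lab]].sum() for lab in ALL_LABELS])
    Z0 = base_w.sum()
    vmeans = np.array([VITALS[v][0] for v in VITALS])
    vsds = np.array([VITALS[v][1] for v in VITALS])
    veff = cfg.vital_effect_scale * np.array([VITALS[v][2] for v in VITALS])

    configs = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    ll = np.zeros((n, 8))
    for q, L in enumerate(configs):
        Lv = np.array(L, dtype=float)
        av = np.r_[Lv, 0.0 if Lv.any() else 1.0]   # active incl. "other"
        z = Z0 + ((np.exp(cfg.gamma) - 1.0) * W * av).sum()
        ll[:, q] += cfg.gamma * (n_sig @ av) - n_events * np.log(z)
        mu = vmeans + veff @ Lv                       # (P,)
        ll[:, q] += ((mu * vital_sums - 0.5 * vital_cnt * mu ** 2) / vsds ** 2).sum(axis=1)
        if cfg.history_signal > 0:
            p = np.where(Lv > 0, cfg.history_signal, cfg.history_background)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll[:, q] += (hist_flags * np.log(p) + (~hist_flags) * np.log(1 - p)).sum(axis=1)
        ll[:, q] += (Lv * np.log(pi) + (1 - Lv) * np.log(1 - pi)).sum()

    cfg_arr = np.array(configs)                        # (8, 3)
    logits = np.zeros((n, 4))
    for j in range(3):
        pos = cfg_arr[:, j] == 1
        logits[:, j] = logsumexp(ll[:, pos], axis=1) - logsumexp(ll[:, ~pos], axis=1)
    none = (cfg_arr.sum(axis=1) == 0)
    logits[:, 3] = logsumexp(ll[:, none], axis=1) - logsumexp(ll[:, ~none], axis=1)
    return logits


def bayes_oracle_auc(cohort: Cohort) -> dict:
    """AUROC of the exact posterior logits against the realised labels —
    the ceiling any classifier trained on this cohort can approach."""
    from sklearn.metrics import roc_auc_score

    y = cohort.labels_array()
    s = cohort.truth.logits
    out = {}
    for j, lab in enumerate(("ahf", "ecopd", "pneumonia", "other")):
        col = y[:, j]
        out[lab] = float(roc_auc_score(col, s[:, j])) if 0 < col.sum() < len(col) else float("nan")
    out["micro"] = float(roc_auc_score(y.ravel(), s.ravel()))
    return out
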