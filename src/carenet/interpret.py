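"""Attention-product variable importance and per-visit attention plots.

The importance of one event occurrence is the product of its three
attention weights — the event's weight within its (period, context) cell,
the cell's context weight within its period, and the period's weight within
the visit.  Occurrences of the same code are summed within a visit, and
visit-level maps are summed over the cohort to rank every code by its
diagnostic contribution.  Continuous and onsite variables bypass the event
attention pathway and are therefore not rankable by this statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ehr import N_RESERVED, Vocabulary
from .network import HierarchyState


@dataclass
class ImportanceRecord:
    rank: int
    code: str
    importance: float


@dataclass
class AttentionPlotData:
    """Bar data for the three-panel attention plot of one visit."""

    period_weights: np.ndarray           # (M,)
    best_period: int
    context_weights: np.ndarray | None   # (6,) of the argmax period
    best_context: int | None
    event_bars: list                     # [(code, weight)] top-n of argmax context
    empty: bool = False

    def to_json(self) -> dict:
        return {
            "period_weights": self.period_weights.tolist(),
            "best_period": self.best_period,
            "context_weights": None if self.context_weights is None
            else self.context_weights.tolist(),
            "best_context": self.best_context,
            "event_bars": [{"code": c, "weight": w} for c, w in self.event_bars],
            "empty": self.empty,
        }


def visit_event_importance(state: HierarchyState, exclude_reserved: bool = True
                           ) -> dict[int, float]:
    """Map token id -> summed triple-product weight for one visit."""
    M, C, L = state.event_attn.shape
    if state.tokens.shape != (M, C, L):
        raise ValueError("state/tokens shape mismatch")
    w = (state.event_attn
         * state.context_attn[:, :, None]
         * state.period_attn[:, None, None]) * state.token_mask
    out: dict[int, float] = {}
    for p in range(M):
        for c in range(C):
            n = int(state.token_mask[p, c].sum())
            for i in range(n):
                tid = int(state.tokens[p, c, i])
                if exclude_reserved and tid < N_RESERVED:
                    continue
                out[tid] = out.get(tid, 0.0) + float(w[p, c, i])
    return out


def cohort_ranking(importances: list[dict[int, float]],
                   vocab: Vocabulary) -> list[ImportanceRecord]:
    """Sum per-code weights over visits; rank descending, ties by code."""
    if not importances:
        raise ValueError("need at least one visit importance map")
    total: dict[int, float] = {}
    for imp in importances:
        for tid, w in imp.items():
            total[tid] = total.get(tid, 0.0) + w
    items = sorted(((vocab.decode(t), w) for t, w in total.items()),
                   key=lambda kv: (-kv[1], kv[0]))
    return [ImportanceRecord(rank=i + 1, code=c, importance=w)
            for i, (c, w) in enumerate(items)]


def write_ranking(records: list[ImportanceRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tcode\timportance\n")
        for r in records:
            fh.write(f"{r.rank}\t{r.code}\t{format(r.importance, '.8g')}\n")


def attention_plot_data(state: HierarchyState, vocab: Vocabulary,
                        top_n: int = 10) -> AttentionPlotData:
    """Select argmax period, argmax context within it, and the top-n events
    of that cell (ties break to the lowest index via argmax)."""
    period_w = state.period_attn.copy()
    best_p = int(np.argmax(period_w))
    if state.cell_mask.sum() == 0:
        return AttentionPlotData(period_weights=period_w, best_period=best_p,
                                 context_weights=None, best_context=None,
                                 event_bars=[], empty=True)
    ctx_w = state.context_attn[best_p].copy()
    # prefer non-empty cells when choosing the context to expand
    masked = np.where(state.cell_mask[best_p] > 0, ctx_w, -np.inf)
    best_c = int(np.argmax(masked)) if np.isfinite(masked).any() else int(np.argmax(ctx_w))
    n = int(state.token_mask[best_p, best_c].sum())
    ev = [(vocab.decode(int(state.tokens[best_p, best_c, i])),
           float(state.event_attn[best_p, best_c, i])) for i in range(n)]
    ev.sort(key=lambda kv: (-kv[1], kv[0]))
    return AttentionPlotData(period_weights=period_w, best_period=best_p,
                             context_weights=ctx_w, best_context=best_c,
                             event_bars=ev[:top_n], empty=False)
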