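"""Event-stream data model: records, labels, timelines, vocabularies, bundles.

An ED "index visit" is classified from everything that happened to the
patient *before* it: time-stamped coded events (diagnoses, complaints,
medications, procedures, binned lab results) from six care contexts, plus
per-period continuous vitals and onsite triage variables.  This module owns
the TSV dialects, the ICD-10 → label mapping, lab binning, segmentation of
the pre-index window into M equal periods, and the packing of one visit
into the ragged tensor bundle the network consumes.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A TSV file violates the documented dialect."""


class Context(enum.IntEnum):
    """The six care contexts events can originate from."""

    PRIMARY_CARE = 0
    OUTPATIENT_SPECIALIST = 1
    ED = 2
    INPATIENT = 3
    AMBULATORY = 4
    OTHERS = 5


N_CONTEXTS = len(Context)
CONTEXT_NAMES = [c.name for c in Context]


class ValueClass(enum.Enum):
    LOW = "LOW"
    NORMAL = "NORMAL"
    HIGH = "HIGH"
    NA = "NA"


@dataclass
class EventRecord:
    patient_id: str
    visit_id: str
    event_time: pd.Timestamp
    context: Context
    code: str
    numeric_value: float | None = None
    value_class: ValueClass | None = None


@dataclass
class IndexVisit:
    visit_id: str
    patient_id: str
    index_time: pd.Timestamp
    onsite: np.ndarray          # fixed-length vector, NaN = missing
    onsite_mask: np.ndarray     # 1 observed / 0 missing
    onsite_names: list[str]
    main_dx_codes: list[str]


@dataclass(frozen=True)
class LabelSet:
    """Multilabel outcome; flags are not mutually exclusive."""

    ahf: bool = False
    ecopd: bool = False
    pneumonia: bool = False
    other: bool = False

    LABELS = ("ahf", "ecopd", "pneumonia", "other")

    def to_array(self) -> np.ndarray:
        return np.array([self.ahf, self.ecopd, self.pneumonia, self.other], dtype=float)

    def __post_init__(self):
        if not (self.ahf or self.ecopd or self.pneumonia or self.other):
            raise ValueError("LabelSet must have at least one flag set")


@dataclass(frozen=True)
class TimelineConfig:
    """Observation window split into ``n_periods`` equal spans ending at the
    index time; period 0 is the most recent."""

    window_weeks: int = 52
    n_periods: int = 10

    def __post_init__(self):
        if self.window_weeks <= 0 or self.n_periods <= 0:
            raise ValueError("window_weeks and n_periods must be positive")

    @property
    def window_seconds(self) -> float:
        return self.window_weeks * 7 * 86400.0

    @property
    def span_seconds(self) -> float:
        return self.window_seconds / self.n_periods


# --------------------------------------------------------------------------
# ICD-10 label mapping
# --------------------------------------------------------------------------

# Normalised (dot-stripped, uppercased) code prefixes per label.
AHF_PREFIXES = ("I110", "I130", "I132", "I50")
ECOPD_PREFIXES = ("J44",)
PNEUMONIA_PREFIXES = ("J100", "J110", "J12", "J13", "J14", "J15", "J16", "J17", "J18")

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


def normalize_icd10(code: str) -> str:
    return code.strip().upper().replace(".", "")


def _matches(norm: str, prefixes: Sequence[str]) -> bool:
    return any(norm.startswith(p) for p in prefixes)


def is_ahf_code(code: str) -> bool:
    return _matches(normalize_icd10(code), AHF_PREFIXES)


def is_ecopd_code(code: str) -> bool:
    return _matches(normalize_icd10(code), ECOPD_PREFIXES)


def is_pneumonia_code(code: str) -> bool:
    return _matches(normalize_icd10(code), PNEUMONIA_PREFIXES)


def map_icd10_to_labelset(codes: Sequence[str]) -> LabelSet:
    """Map the main-diagnosis ICD-10 codes of a visit to the four labels.

    Acute heart failure is I11.0, I13.0, I13.2 or I50 (any subcode);
    exacerbated COPD is J44; pneumonia is J10.0, J11.0 or J12–J18.  Any code
    outside those sets raises the "other" flag, so the mapping is total and
    more than one label is allowed.
    """
    if not codes:
        raise ValueError("no main diagnosis: ICD-10 code list is empty")
    ahf = ecopd = pneu = other = False
    for code in codes:
        norm = normalize_icd10(code)
        if not _ICD10_RE.match(norm):
            raise ValueError(f"malformed ICD-10 code: {code!r}")
        hit = False
        if _matches(norm, AHF_PREFIXES):
            ahf, hit = True, True
        if _matches(norm, ECOPD_PREFIXES):
            ecopd, hit = True, True
        if _matches(norm, PNEUMONIA_PREFIXES):
            pneu, hit = True, True
        if not hit:
            other = True
    return LabelSet(ahf=ahf, ecopd=ecopd, pneumonia=pneu, other=other)


def bin_lab_value(value: float | None, ref_low: float, ref_high: float) -> ValueClass:
    """Classify a lab value against its reference interval.

    Boundaries are inclusive in NORMAL; a missing value maps to NA.
    """
    if ref_low >= ref_high:
        raise ValueError(f"reference interval invalid: [{ref_low}, {ref_high}]")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ValueClass.NA
    if value < ref_low:
        return ValueClass.LOW
    if value > ref_high:
        return ValueClass.HIGH
    return ValueClass.NORMAL


# --------------------------------------------------------------------------
# Timeline segmentation
# --------------------------------------------------------------------------

DROPPED = -1


def period_of(age_seconds: float, cfg: TimelineConfig) -> int:
    """Period index for an event ``age_seconds`` before the index time, or
    DROPPED (-1) if it falls outside the observation window."""
    if age_seconds < 0:
        raise ValueError("event after index")
    if age_seconds >= cfg.window_seconds:
        return DROPPED
    return int(age_seconds // cfg.span_seconds)


def segment_timeline(events: Sequence[EventRecord], index_time: pd.Timestamp,
                     cfg: TimelineConfig) -> list[int]:
    """Assign each event a period index (0 = most recent) or DROPPED.

    Raises if any event is at or after the index time.
    """
    out = []
    for ev in events:
        age = (index_time - ev.event_time).total_seconds()
        if age <= 0:
            raise ValueError(f"event after index: {ev.code} at {ev.event_time}")
        out.append(period_of(age, cfg))
    return out


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

EMPTY_TOKEN = "<EMPTY>"
NA_TOKEN = "<NA>"
EMPTY_ID = 0
NA_ID = 1
N_RESERVED = 2


class Vocabulary:
    """Bijection between event-code strings and integer ids.

    Ids 0 and 1 are reserved for the EMPTY-cell token and the NA token
    (unknown or below-min-count codes).  Non-reserved codes are assigned ids
    in lexicographic order, so construction is deterministic.
    """

    def __init__(self, codes: Iterable[str]):
        self._code_to_id: dict[str, int] = {EMPTY_TOKEN: EMPTY_ID, NA_TOKEN: NA_ID}
        for i, code in enumerate(sorted(set(codes))):
            self._code_to_id[code] = N_RESERVED + i
        self._id_to_code = {v: k for k, v in self._code_to_id.items()}

    def __len__(self) -> int:
        return len(self._code_to_id)

    def __contains__(self, code: str) -> bool:
        return code in self._code_to_id

    def encode(self, code: str) -> int:
        return self._code_to_id.get(code, NA_ID)

    def decode(self, idx: int) -> str:
        return self._id_to_code[idx]

    @property
    def codes(self) -> list[str]:
        return [self._id_to_code[i] for i in range(N_RESERVED, len(self))]


def build_vocabulary(events, min_count: int = 5) -> Vocabulary:
    """Build a vocabulary from an event stream, dropping codes whose corpus
    frequency is below ``min_count`` (they encode to the NA token)."""
    if isinstance(events, pd.DataFrame):
        counts = events["code"].value_counts()
    else:
        counts = pd.Series([ev.code for ev in events]).value_counts() if events else pd.Series(dtype=int)
    kept = counts[counts >= min_count].index
    return Vocabulary(kept)


# --------------------------------------------------------------------------
# Visit bundles
# --------------------------------------------------------------------------


@dataclass
class VisitTensorBundle:
    """One visit packed for the network: ragged token ids per (period,
    context) cell, per-period numeric variables with an observed mask, the
    onsite vector, and the labels."""

    visit_id: str
    tokens: list          # [M][N_CONTEXTS] -> list[int]
    period_numeric: np.ndarray   # (M, P) values, 0 where unobserved
    period_mask: np.ndarray      # (M, P) 1 observed / 0 missing
    onsite_numeric: np.ndarray   # (Q,)
    onsite_mask: np.ndarray      # (Q,)
    labels: LabelSet | None
    meta: dict = field(default_factory=dict)

    @property
    def n_periods(self) -> int:
        return len(self.tokens)

    def is_empty(self) -> bool:
        return all(not cell for row in self.tokens for cell in row)


DEFAULT_NUMERIC_CODES = ["VITAL:TEMP", "VITAL:HR", "VITAL:RESP", "VITAL:SBP", "VITAL:SPO2"]


def build_bundle(events: Sequence[EventRecord], visit: IndexVisit, vocab: Vocabulary,
                 cfg: TimelineConfig,
                 numeric_codes: Sequence[str] | None = None) -> VisitTensorBundle:
    """Pack one visit's prior events into a :class:`VisitTensorBundle`.

    Events are grouped by (period, context) and ordered chronologically
    within a cell (ties broken by code string, so the result is invariant to
    input row order).  Codes listed in ``numeric_codes`` feed the per-period
    continuous channel — last observation in the period wins — instead of
    the token sequences.  Unknown codes encode to the NA token.  A visit
    with no usable prior events yields an all-EMPTY bundle.
    """
    if numeric_codes is None:
        numeric_codes = DEFAULT_NUMERIC_CODES
    numeric_index = {c: i for i, c in enumerate(numeric_codes)}
    M = cfg.n_periods
    P = len(numeric_codes)
    tokens = [[[] for _ in range(N_CONTEXTS)] for _ in range(M)]
    pnum = np.zeros((M, P))
    pmask = np.zeros((M, P))
    # latest observation time seen per (period, variable)
    latest = np.full((M, P), -np.inf)
    ordered = sorted(events, key=lambda ev: (ev.event_time, ev.code))
    for ev in ordered:
        age = (visit.index_time - ev.event_time).total_seconds()
        if age <= 0:
            raise ValueError(f"event after index: {ev.code} at {ev.event_time}")
        p = period_of(age, cfg)
        if p == DROPPED:
            continue
        j = numeric_index.get(ev.code)
        if j is not None:
            if ev.numeric_value is not None and not np.isnan(ev.numeric_value):
                t = ev.event_time.timestamp()
                if t >= latest[p, j]:
                    latest[p, j] = t
                    pnum[p, j] = ev.numeric_value
                    pmask[p, j] = 1.0
            continue
        tokens[p][ev.context].append(vocab.encode(ev.code))
    labels = map_icd10_to_labelset(visit.main_dx_codes) if visit.main_dx_codes else None
    return VisitTensorBundle(
        visit_id=visit.visit_id,
        tokens=tokens,
        period_numeric=pnum,
        period_mask=pmask,
        onsite_numeric=np.where(visit.onsite_mask > 0, visit.onsite, 0.0),
        onsite_mask=visit.onsite_mask.astype(float),
        labels=labels,
        meta={"patient_id": visit.patient_id, "onsite_names": visit.onsite_names},
    )


def build_bundles(events_df: pd.DataFrame, visits: Sequence[IndexVisit],
                  vocab: Vocabulary, cfg: TimelineConfig,
                  numeric_codes: Sequence[str] | None = None) -> list[VisitTensorBundle]:
    """Vectorised cohort-scale bundle construction (same semantics as
    repeated :func:`build_bundle`, which is the reference implementation)."""
    if numeric_codes is None:
        numeric_codes = DEFAULT_NUMERIC_CODES
    numeric_set = set(numeric_codes)
    numeric_index = {c: i for i, c in enumerate(numeric_codes)}
    M = cfg.n_periods
    P = len(numeric_codes)
    vmap = {v.visit_id: v for v in visits}

    bundles = {}
    for v in visits:
        bundles[v.visit_id] = VisitTensorBundle(
            visit_id=v.visit_id,
            tokens=[[[] for _ in range(N_CONTEXTS)] for _ in range(M)],
            period_numeric=np.zeros((M, P)),
            period_mask=np.zeros((M, P)),
            onsite_numeric=np.where(v.onsite_mask > 0, v.onsite, 0.0),
            onsite_mask=v.onsite_mask.astype(float),
            labels=map_icd10_to_labelset(v.main_dx_codes) if v.main_dx_codes else None,
            meta={"patient_id": v.patient_id, "onsite_names": v.onsite_names},
        )
    if events_df.empty:
        return [bundles[v.visit_id] for v in visits]

    df = events_df.copy()
    idx_time = df["visit_id"].map({k: v.index_time for k, v in vmap.items()})
    if idx_time.isna().any():
        df = df[~idx_time.isna()]
        idx_time = idx_time.dropna()
    age = (pd.to_datetime(idx_time.values) - pd.to_datetime(df["event_time"].values)).total_seconds()
    if np.any(age <= 0):
        bad = df.iloc[int(np.argmax(age <= 0))]
        raise ValueError(f"event after index: {bad['code']} at {bad['event_time']}")
    period = np.floor(age / cfg.span_seconds).astype(int)
    keep = age < cfg.window_seconds
    df = df.assign(_period=period, _age=age)[keep]

    is_numeric = df["code"].isin(numeric_set)
    # numeric channel: last observation per (visit, period, variable)
    num = df[is_numeric].dropna(subset=["numeric_value"])
    if not num.empty:
        num = num.sort_values(["visit_id", "event_time", "code"])
        grp = num.groupby(["visit_id", "_period", "code"], sort=False).tail(1)
        for vid, p, code, val in zip(grp["visit_id"], grp["_period"], grp["code"],
                                     grp["numeric_value"]):
            j = numeric_index[code]
            b = bundles[vid]
            b.period_numeric[p, j] = val
            b.period_mask[p, j] = 1.0

    tok = df[~is_numeric].copy()
    if not tok.empty:
        tok["_tid"] = tok["code"].map(vocab.encode).astype(np.int64)
        tok = tok.sort_values(["visit_id", "_period", "context", "event_time", "code"],
                              kind="mergesort")
        for (vid, p, c), g in tok.groupby(["visit_id", "_period", "context"], sort=False):
            ci = int(Context[c]) if isinstance(c, str) else int(c)
            bundles[vid].tokens[p][ci] = g["_tid"].tolist()
    return [bundles[v.visit_id] for v in visits]


# --------------------------------------------------------------------------
# TSV I/O
# --------------------------------------------------------------------------

EVENT_COLUMNS = ["patient_id", "visit_id", "event_time", "context", "code",
                 "value_class", "numeric_value"]
VISIT_FIXED_COLUMNS = ["visit_id", "patient_id", "index_time", "main_dx_codes"]

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


def read_event_frame(path) -> pd.DataFrame:
    """Read events.tsv into a validated DataFrame (the cohort-scale path)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != EVENT_COLUMNS:
        raise SchemaError(f"events file {path}: expected columns {EVENT_COLUMNS}, "
                          f"got {list(df.columns)}")
    if df.empty:
        df["event_time"] = pd.to_datetime(df["event_time"])
        df["numeric_value"] = pd.Series(dtype=float)
        return df
    times = pd.to_datetime(df["event_time"], format=_TIME_FMT, errors="coerce")
    if times.isna().any():
        line = int(times.isna().idxmax()) + 2
        raise SchemaError(f"events file {path}, line {line}: bad timestamp "
                          f"{df['event_time'].iloc[line - 2]!r}")
    bad_ctx = ~df["context"].isin(CONTEXT_NAMES)
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 2
        raise SchemaError(f"events file {path}, line {line}: unknown context "
                          f"{df['context'].iloc[line - 2]!r}")
    if (df["code"] == "").any():
        line = int((df["code"] == "").idxmax()) + 2
        raise SchemaError(f"events file {path}, line {line}: empty code")
    out = df.copy()
    out["event_time"] = times
    out["numeric_value"] = pd.to_numeric(df["numeric_value"].mask(
        df["numeric_value"] == "", np.nan))
    return out


def read_event_stream(path) -> list[EventRecord]:
    """Read events.tsv into a list of :class:`EventRecord`."""
    df = read_event_frame(path)
    records = []
    for row in df.itertuples(index=False):
        nv = row.numeric_value
        records.append(EventRecord(
            patient_id=row.patient_id,
            visit_id=row.visit_id,
            event_time=row.event_time,
            context=Context[row.context],
            code=row.code,
            numeric_value=None if pd.isna(nv) else float(nv),
            value_class=ValueClass[row.value_class] if row.value_class else None,
        ))
    return records


def _fmt_num(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    return format(float(v), ".10g")


def write_event_stream(events, path) -> None:
    """Write events in the canonical dialect (round-trips byte-identically)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        if isinstance(events, pd.DataFrame):
            it = (EventRecord(r.patient_id, r.visit_id, pd.Timestamp(r.event_time),
                              Context[r.context] if isinstance(r.context, str) else Context(r.context),
                              r.code,
                              None if pd.isna(r.numeric_value) else float(r.numeric_value),
                              ValueClass[r.value_class] if r.value_class else None)
                  for r in events.itertuples(index=False))
        else:
            it = iter(events)
        for ev in it:
            fh.write("\t".join([
                ev.patient_id, ev.visit_id,
                ev.event_time.strftime(_TIME_FMT),
                ev.context.name, ev.code,
                ev.value_class.value if ev.value_class else "",
                _fmt_num(ev.numeric_value),
            ]) + "\n")


def read_index_visits(path) -> list[IndexVisit]:
    """Read visits.tsv; onsite variables are every ``onsite_*`` column, in
    file order, with empty cells treated as missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in VISIT_FIXED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"visits file {path}: missing column {col!r}")
    onsite_cols = [c for c in df.columns if c.startswith("onsite_")]
    names = [c[len("onsite_"):] for c in onsite_cols]
    visits = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        try:
            t = pd.to_datetime(d["index_time"], format=_TIME_FMT)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"visits file {path}, line {i + 2}: bad index_time") from exc
        raw = [d[c] for c in onsite_cols]
        vals = np.array([float(x) if x != "" else np.nan for x in raw])
        codes = [c for c in d["main_dx_codes"].split(";") if c]
        visits.append(IndexVisit(
            visit_id=d["visit_id"], patient_id=d["patient_id"], index_time=t,
            onsite=np.nan_to_num(vals), onsite_mask=(~np.isnan(vals)).astype(float),
            onsite_names=names, main_dx_codes=codes,
        ))
    return visits


def write_index_visits(visits: Sequence[IndexVisit], path) -> None:
    names = visits[0].onsite_names if visits else []
    cols = VISIT_FIXED_COLUMNS + [f"onsite_{n}" for n in names]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in visits:
            onsite = [_fmt_num(val) if m > 0 else ""
                      for val, m in zip(v.onsite, v.onsite_mask)]
            fh.write("\t".join([v.visit_id, v.patient_id,
                                v.index_time.strftime(_TIME_FMT),
                                ";".join(v.main_dx_codes)] + onsite) + "\n")
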