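"""Cohort selection, observation windows, SOEP documents and the data split.

Patients enter the cohort only if they are older than 30 years at the index
date and (for cases) enrolled at least five months before diagnosis with at
least one note before it.  Cases contribute the two years of history ending
five months before diagnosis; controls the matching two years ending one
month before their last GP visit.  Every in-window visit becomes one
"sentence": the literal SOEP marker tokens S, O, E, P each followed by that
field's tokens.  Documents whose total word count exceeds the empirical
99.7th percentile (the 3-sigma rule) are excluded.  Finally the cohort is
split 60/20/20 into train/tune/test folds, stratified on the outcome.

Months are 30-day intervals throughout (deterministic, calendar-free).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthetic import (ICPC_CODES, PatientRecord, Visit,
                        case_window, control_window)

__all__ = [
    "Document", "StructuredPredictors", "SplitAssignment",
    "apply_inclusion_criteria", "extract_observation_window",
    "build_document", "exclude_long_documents", "stratified_split",
    "prepare_documents", "tokenize", "write_documents", "read_documents",
    "write_split", "read_split", "MIN_AGE_YEARS", "ENROLLMENT_LEAD_MONTHS",
]

MIN_AGE_YEARS = 30.0
ENROLLMENT_LEAD_MONTHS = 5
_DAYS_PER_YEAR = 365.25
_MONTH = 30  # days

SOEP_MARKERS = ("S", "O", "E", "P")


@dataclass
class StructuredPredictors:
    """Age, sex and windowed ICPC counts, in fixed order (13 predictors)."""

    age: float
    sex: int                      # 1 = male, 0 = female
    icpc_counts: tuple[int, ...]  # aligned with ICPC_CODES

    def as_vector(self) -> np.ndarray:
        return np.array([self.age, self.sex, *self.icpc_counts], dtype=float)


@dataclass
class Document:
    patient_id: str
    sentences: list[list[str]]          # one per in-window visit, date order
    structured: StructuredPredictors
    label: int
    sentence_dates: list[date] = field(default_factory=list)

    @property
    def word_count(self) -> int:
        return sum(len(s) for s in self.sentences)


@dataclass
class SplitAssignment:
    assignment: dict[str, str]          # patient_id -> train|tune|test
    split_seed: int

    def fold(self, name: str) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f == name]


# ------------------------------------------------------------- tokenisation
_STRIP = ".,;:!?()[]{}\"'`«»<>/\\|"


def tokenize(text: str) -> list[str]:
    """Lowercase, whitespace-split, strip edge punctuation, keep hyphens."""
    out = []
    for raw in text.lower().split():
        tok = raw.strip(_STRIP)
        if tok:
            out.append(tok)
    return out


# ---------------------------------------------------------------- inclusion
def _age_at(birth: date, when: date) -> float:
    return (when - birth).days / _DAYS_PER_YEAR


def apply_inclusion_criteria(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Retain adults (>30y at index) and, for cases, patients with at least
    one pre-diagnosis note who enrolled >= 5 months before diagnosis."""
    kept = []
    for r in records:
        if not r.visits:
            continue
        if _age_at(r.birth_date, r.index_date) <= MIN_AGE_YEARS:
            continue
        if r.diagnosis_date is not None:
            pre = [v for v in r.visits if v.date < r.diagnosis_date]
            if not pre:
                continue
            enrolled = min(v.date for v in r.visits)
            if (r.diagnosis_date - enrolled).days < ENROLLMENT_LEAD_MONTHS * _MONTH:
                continue
        kept.append(r)
    return kept


def extract_observation_window(record: PatientRecord) -> PatientRecord | None:
    """Filter visits to the observation window; ``None`` when none remain."""
    lo, hi = (case_window(record.diagnosis_date)
              if record.diagnosis_date is not None
              else control_window(record.last_visit_date))
    visits = [v for v in record.visits if lo <= v.date <= hi]
    if not visits:
        return None
    return replace(record, visits=visits)


# ---------------------------------------------------------------- documents
def _visit_sentence(v: Visit) -> list[str]:
    sent: list[str] = []
    for marker, toks in zip(SOEP_MARKERS,
                            (v.s_field, v.o_field, v.e_field, v.p_field)):
        sent.append(marker)
        sent.extend(toks)
    return sent


def build_document(record: PatientRecord) -> Document:
    """One sentence per windowed visit, SOEP markers kept as literal tokens;
    structured predictors computed at the index date with ICPC counts
    restricted to the same window."""
    visits = sorted(record.visits, key=lambda v: v.date)
    lo, hi = (case_window(record.diagnosis_date)
              if record.diagnosis_date is not None
              else control_window(record.last_visit_date))
    counts = {c: 0 for c in ICPC_CODES}
    for code, d in record.icpc_events:
        if code in counts and lo <= d <= hi:
            counts[code] += 1
    structured = StructuredPredictors(
        age=_age_at(record.birth_date, record.index_date),
        sex=1 if record.sex == "male" else 0,
        icpc_counts=tuple(counts[c] for c in ICPC_CODES),
    )
    return Document(
        patient_id=record.patient_id,
        sentences=[_visit_sentence(v) for v in visits],
        structured=structured,
        label=record.label,
        sentence_dates=[v.date for v in visits],
    )


def exclude_long_documents(documents: Sequence[Document],
                           quantile: float = 0.997) -> list[Document]:
    """Drop documents strictly above the empirical length quantile."""
    if not documents:
        raise ValueError("no documents to filter")
    counts = np.array([d.word_count for d in documents], dtype=float)
    cutoff = float(np.quantile(counts, quantile))
    return [d for d, c in zip(documents, counts) if c <= cutoff]


def prepare_documents(records: Iterable[PatientRecord],
                      length_quantile: float = 0.997) -> list[Document]:
    """Full preparation chain: inclusion -> windowing -> documents -> length cut."""
    docs = []
    for r in apply_inclusion_criteria(records):
        windowed = extract_observation_window(r)
        if windowed is not None:
            docs.append(build_document(windowed))
    if not docs:
        return []
    return exclude_long_documents(docs, quantile=length_quantile)


# -------------------------------------------------------------------- split
_FOLDS = ("train", "tune", "test")
_FRACTIONS = (0.6, 0.2, 0.2)


def stratified_split(documents: Sequence[Document], seed: int) -> SplitAssignment:
    """60/20/20 outcome-stratified patient split, reproducible given seed."""
    if len(documents) < 5:
        raise ValueError("need at least 5 documents to split")
    labels = {d.label for d in documents}
    if len(labels) > 1:
        n_cases = sum(d.label for d in documents)
        if n_cases < len(_FOLDS):
            raise ValueError(
                f"need at least {len(_FOLDS)} cases to stratify, got {n_cases}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in sorted(labels):
        ids = sorted(d.patient_id for d in documents if d.label == label)
        rng.shuffle(ids)
        n = len(ids)
        sizes = _largest_remainder(n, _FRACTIONS)
        start = 0
        for fold, size in zip(_FOLDS, sizes):
            for pid in ids[start:start + size]:
                assignment[pid] = fold
            start += size
    return SplitAssignment(assignment=assignment, split_seed=seed)


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    remainder = n - sum(sizes)
    order = sorted(range(len(fractions)),
                   key=lambda i: (raw[i] - sizes[i]), reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


# ------------------------------------------------------------------------ IO
def write_documents(documents: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in documents:
            fh.write(json.dumps({
                "patient_id": d.patient_id,
                "sentences": d.sentences,
                "sentence_dates": [x.isoformat() for x in d.sentence_dates],
                "age": d.structured.age,
                "sex": d.structured.sex,
                "icpc_counts": list(d.structured.icpc_counts),
                "label": d.label,
            }, sort_keys=True) + "\n")


def read_documents(path: str | Path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            o = json.loads(line)
            docs.append(Document(
                patient_id=o["patient_id"],
                sentences=[list(s) for s in o["sentences"]],
                structured=StructuredPredictors(
                    age=float(o["age"]), sex=int(o["sex"]),
                    icpc_counts=tuple(int(c) for c in o["icpc_counts"])),
                label=int(o["label"]),
                sentence_dates=[date.fromisoformat(x)
                                for x in o.get("sentence_dates", [])],
            ))
    return docs


def write_split(split: SplitAssignment, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "fold"])
        for pid in sorted(split.assignment):
            w.writerow([pid, split.assignment[pid]])


def read_split(path: str | Path, seed: int = -1) -> SplitAssignment:
    assignment = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            assignment[row["patient_id"]] = row["fold"]
    return SplitAssignment(assignment=assignment, split_seed=seed)
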