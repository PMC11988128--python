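"""Synthetic longitudinal SOEP-note cohorts with planted, window-aware signal.

The study data — Dutch GP consultation notes linked to a national cancer
registry — are private, so every downstream stage of the pipeline is exercised
on simulated cohorts whose generative process is fully known.  The generator
emulates the features that matter to the model and its evaluation:

* a rare outcome (default prevalence 0.4%),
* an age shift between cases and controls (median ~68 vs ~52 years),
* multi-year visit histories with SOEP-structured token streams,
* case-enriched "signal" tokens emitted preferentially inside the
  observation window that cohort preparation will later select, and
* per-code Poisson counts of lung-cancer-associated ICPC events, elevated
  in cases.

Background text is drawn from a Zipf-like distribution over a synthetic
Dutch-looking vocabulary; it makes no claim of linguistic realism, only of
heavy-tailed token frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ICPC_CODES", "MONTH_DAYS", "GeneratorConfig", "Visit", "PatientRecord",
    "generate_corpus", "write_corpus", "read_corpus", "make_vocabulary",
    "case_window", "control_window", "ConfigError", "CorpusParseError",
]

#: ICPC codes used as structured predictors, in fixed reporting order.
ICPC_CODES = ("A04", "B80", "B82", "P17", "R02", "R05",
              "R24", "R95", "T03", "T08", "L04")

#: Window arithmetic uses 30-day months (deterministic, calendar-free).
MONTH_DAYS = 30

#: Case window: two years of history ending five months before diagnosis.
CASE_WINDOW_MONTHS = (29, 5)
#: Control window: the same two years, ending one month before the last visit.
CONTROL_WINDOW_MONTHS = (25, 1)

_REFERENCE_DATE = date(2020, 1, 1)

_SYLLABLES = (
    "ver", "ge", "be", "ont", "her", "lijk", "ing", "heid", "acht", "ster",
    "klacht", "pijn", "long", "keel", "huis", "arts", "zorg", "dag", "week",
    "maand", "bloed", "druk", "hart", "maag", "rug", "been", "arm", "hoofd",
    "oor", "oog", "neus", "mond", "huid", "koorts", "moe", "zwak", "licht",
    "zwaar", "goed", "slecht",
)

DEFAULT_SIGNAL_TOKENS = ("hoesten", "bloedophoesten", "kortademig",
                         "vermoeidheid", "gewichtsverlies")


class ConfigError(ValueError):
    """Invalid generator configuration."""


class CorpusParseError(ValueError):
    """Malformed corpus file; carries the offending line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def case_window(diagnosis: date) -> tuple[date, date]:
    lo, hi = CASE_WINDOW_MONTHS
    return (diagnosis - timedelta(days=lo * MONTH_DAYS),
            diagnosis - timedelta(days=hi * MONTH_DAYS))


def control_window(last_visit: date) -> tuple[date, date]:
    lo, hi = CONTROL_WINDOW_MONTHS
    return (last_visit - timedelta(days=lo * MONTH_DAYS),
            last_visit - timedelta(days=hi * MONTH_DAYS))


def make_vocabulary(size: int) -> list[str]:
    """Deterministic synthetic vocabulary of ``size`` unique pseudo-words."""
    words: list[str] = []
    seen: set[str] = set()
    n = len(_SYLLABLES)
    r = 0
    while len(words) < size:
        parts = [_SYLLABLES[r % n], _SYLLABLES[(r // n) % n]]
        if r >= n * n:
            parts.append(_SYLLABLES[(r // (n * n)) % n])
        w = "".join(parts)
        if w not in seen:
            seen.add(w)
            words.append(w)
        r += 1
    return words


# --------------------------------------------------------------------- types
@dataclass
class Visit:
    date: date
    s_field: list[str] = field(default_factory=list)
    o_field: list[str] = field(default_factory=list)
    e_field: list[str] = field(default_factory=list)
    p_field: list[str] = field(default_factory=list)


@dataclass
class PatientRecord:
    patient_id: str
    sex: str                       # "female" | "male"
    birth_date: date
    visits: list[Visit]
    icpc_events: list[tuple[str, date]]
    diagnosis_date: date | None
    last_visit_date: date
    label: int

    @property
    def index_date(self) -> date:
        """Window anchor: diagnosis for cases, last GP visit for controls."""
        return self.diagnosis_date if self.diagnosis_date is not None \
            else self.last_visit_date


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults emulate the study conditions."""

    n_patients: int = 20_000
    prevalence: float = 0.004
    seed: int = 0
    vocab_size_background: int = 2000
    zipf_exponent: float = 1.07
    signal_tokens: Sequence[str] = DEFAULT_SIGNAL_TOKENS
    signal_rate_case: float = 0.30        # per in-window case sentence
    signal_rate_control: float = 0.01     # elsewhere
    signal_field_s_share: float = 0.7     # S vs E placement of signal tokens
    visits_per_patient: tuple[float, float] = (8.0, 4.0)   # NB mean, dispersion
    words_per_field: tuple[float] = (5.0,)                  # Poisson mean
    age_params_case: tuple[float, float] = (68.0, 11.0)     # loc, scale (years)
    age_params_control: tuple[float, float] = (52.0, 17.8)
    icpc_rate_case: float | Mapping[str, float] = 0.6       # Poisson mean/code
    icpc_rate_control: float | Mapping[str, float] = 0.2
    span_months: int = 36

    def validate(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"prevalence must be in [0,1], got {self.prevalence}")
        if not 0.0 <= self.signal_rate_control <= self.signal_rate_case <= 1.0:
            raise ConfigError("need 0 <= signal_rate_control <= signal_rate_case <= 1")
        for name in ("n_patients", "vocab_size_background", "span_months"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.visits_per_patient[0] <= 0 or self.words_per_field[0] <= 0:
            raise ConfigError("distribution means must be positive")

    def icpc_rates(self, label: int) -> dict[str, float]:
        raw = self.icpc_rate_case if label else self.icpc_rate_control
        if isinstance(raw, Mapping):
            return {c: float(raw.get(c, 0.0)) for c in ICPC_CODES}
        return {c: float(raw) for c in ICPC_CODES}


# ----------------------------------------------------------------- generator
def _zipf_weights(size: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, size + 1) ** exponent
    return w / w.sum()


def generate_corpus(config: GeneratorConfig) -> list[PatientRecord]:
    """Draw a full synthetic cohort; reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = np.array(make_vocabulary(config.vocab_size_background))
    weights = _zipf_weights(config.vocab_size_background, config.zipf_exponent)
    nb_mean, nb_disp = config.visits_per_patient
    wpf_mean = config.words_per_field[0]
    signal = list(config.signal_tokens)
    labels = (rng.random(config.n_patients) < config.prevalence).astype(int)

    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        label = int(labels[i])
        anchor = _REFERENCE_DATE - timedelta(days=int(rng.integers(0, 365)))

        # visit count: gamma-poisson mixture (negative binomial), >= 1
        lam = rng.gamma(shape=nb_disp, scale=nb_mean / nb_disp)
        n_visits = max(1, int(rng.poisson(lam)))
        offsets = np.sort(rng.integers(0, config.span_months * MONTH_DAYS,
                                       size=n_visits))[::-1]
        dates = [anchor - timedelta(days=int(d)) for d in offsets]
        dates.sort()
        last_visit = dates[-1]
        diagnosis = anchor if label else None
        win_lo, win_hi = (case_window(diagnosis) if label
                          else control_window(last_visit))

        visits = []
        for d in dates:
            fields = [_sample_field(rng, vocab, weights, wpf_mean)
                      for _ in range(4)]
            in_window = win_lo <= d <= win_hi
            rate = (config.signal_rate_case if (label and in_window)
                    else config.signal_rate_control)
            if rate > 0 and rng.random() < rate:
                tok = signal[int(rng.integers(0, len(signal)))]
                which = 0 if rng.random() < config.signal_field_s_share else 2
                pos = int(rng.integers(0, len(fields[which]) + 1))
                fields[which].insert(pos, tok)
            visits.append(Visit(d, *fields))

        rates = config.icpc_rates(label)
        span_days = (win_hi - win_lo).days
        events: list[tuple[str, date]] = []
        for code in ICPC_CODES:
            for _ in range(int(rng.poisson(rates[code]))):
                events.append((code, win_lo + timedelta(
                    days=int(rng.integers(0, span_days + 1)))))
        events.sort(key=lambda e: (e[1], e[0]))

        loc, scale = (config.age_params_case if label
                      else config.age_params_control)
        age = float(rng.normal(loc, scale))
        index = diagnosis if label else last_visit
        birth = index - timedelta(days=int(round(max(age, 1.0) * 365.25)))

        records.append(PatientRecord(
            patient_id=f"p{i:06d}",
            sex="female" if rng.random() < 0.5 else "male",
            birth_date=birth,
            visits=visits,
            icpc_events=events,
            diagnosis_date=diagnosis,
            last_visit_date=last_visit,
            label=label,
        ))
    return records


def _sample_field(rng: np.random.Generator, vocab: np.ndarray,
                  weights: np.ndarray, mean: float) -> list[str]:
    k = int(rng.poisson(mean))
    if k == 0:
        return []
    return list(vocab[rng.choice(len(vocab), size=k, p=weights)])


# ------------------------------------------------------------------------ IO
def _record_to_json(r: PatientRecord) -> dict:
    d = {
        "patient_id": r.patient_id,
        "sex": r.sex,
        "birth_date": r.birth_date.isoformat(),
        "visits": [{
            "date": v.date.isoformat(),
            "s": v.s_field, "o": v.o_field, "e": v.e_field, "p": v.p_field,
        } for v in r.visits],
        "icpc_events": [[c, d_.isoformat()] for c, d_ in r.icpc_events],
        "last_visit_date": r.last_visit_date.isoformat(),
        "label": r.label,
    }
    if r.diagnosis_date is not None:
        d["diagnosis_date"] = r.diagnosis_date.isoformat()
    return d


def _record_from_json(obj: dict) -> PatientRecord:
    diag = obj.get("diagnosis_date")
    return PatientRecord(
        patient_id=obj["patient_id"],
        sex=obj["sex"],
        birth_date=date.fromisoformat(obj["birth_date"]),
        visits=[Visit(date.fromisoformat(v["date"]),
                      list(v["s"]), list(v["o"]), list(v["e"]), list(v["p"]))
                for v in obj["visits"]],
        icpc_events=[(c, date.fromisoformat(d_)) for c, d_ in obj["icpc_events"]],
        diagnosis_date=date.fromisoformat(diag) if diag is not None else None,
        last_visit_date=date.fromisoformat(obj["last_visit_date"]),
        label=int(obj["label"]),
    )


def write_corpus(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write one JSON record per line (dates ISO-8601)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(_record_to_json(r), sort_keys=True) + "\n")


def read_corpus(path: str | Path) -> list[PatientRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(_record_from_json(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as e:
                raise CorpusParseError(i, str(e)) from e
    return records
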