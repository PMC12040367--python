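"""Patient selection, index dates, and 24-month observation windows.

The case-finding design anchors every patient at an *index date*:

* cases — the mid-date (day 15) of the registry diagnosis month, shifted
  back by the lead time (default 5 calendar months), so the model only
  sees information available well before the diagnosis was registered;
* controls — one calendar month before the last recorded GP contact.

The observation window is the half-open 24-month interval
``[index_date - 24 months, index_date)``; notes and coded episodes dated
exactly at the index date are excluded.  Selection keeps patients aged
>= 40 years at index with at least 24 months of record span before the
index date and at least one non-empty note in the window, and logs a
step table of exclusions (first matching reason wins, in the fixed
order age -> history -> text).
"""

from __future__ import annotations

import datetime as dt
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from ._dates import add_months, mid_month

# ICPC symptom codes considered as candidate coded predictors of lung
# cancer, and the subset retained by backward AIC elimination in the
# reference analysis: B02 enlarged lymph nodes, D01 generalised abdominal
# pain, P17 nicotine dependence, T03 reduced appetite, T08 weight loss.
SELECTED_CODES = ("B02", "D01", "P17", "T03", "T08")
CANDIDATE_ONLY_CODES = (
    "A04",  # fatigue
    "B80",  # iron-deficiency anaemia
    "B82",  # other anaemia
    "D87",  # dyspepsia / indigestion
    "K94",  # thrombophlebitis / phlebothrombosis
    "L04",  # chest pain
    "R02",  # dyspnoea
    "R05",  # cough
    "R24",  # haemoptysis
    "R81",  # pneumonia
)


@dataclass(frozen=True)
class IcpcCatalogue:
    """Candidate ICPC predictor codes and the retained subset."""

    selected: tuple[str, ...] = SELECTED_CODES
    candidate_only: tuple[str, ...] = CANDIDATE_ONLY_CODES

    @property
    def candidates(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.selected) | set(self.candidate_only)))

    def __post_init__(self) -> None:
        if set(self.selected) & set(self.candidate_only):
            raise ValueError("selected and candidate_only overlap")


DEFAULT_CATALOGUE = IcpcCatalogue()

_NUM_RE = re.compile(r"\d+(?:[.,]\d+)*")
_PUNCT_RE = re.compile(r"[^\w\s<>]", flags=re.UNICODE)

NUM_TOKEN = "<num>"


def normalize_text(raw: str) -> list[str]:
    """Lowercase, map digit runs to ``<num>``, strip punctuation, split.

    Deterministic and idempotent: ``normalize(" ".join(normalize(x)))``
    equals ``normalize(x)``.
    """
    s = raw.lower()
    s = _NUM_RE.sub(f" {NUM_TOKEN} ", s)
    s = _PUNCT_RE.sub(" ", s)
    return s.split()


def index_date_for_case(diagnosis_month: str, lead_months: int = 5) -> dt.date:
    """Index date for a case: mid-month of diagnosis minus the lead time.

    Lead times outside the 2-6 month sensitivity grid are allowed (any
    positive integer) but warned about.
    """
    if lead_months < 0:
        raise ValueError("lead_months must be >= 0")
    if lead_months not in (0, 2, 3, 4, 5, 6):
        warnings.warn(
            f"lead_months={lead_months} is outside the 2-6 month "
            "sensitivity grid",
            stacklevel=2,
        )
    return add_months(mid_month(diagnosis_month), -lead_months)


def index_date_for_control(last_visit_date: dt.date) -> dt.date:
    """Index date for a control: one calendar month before the last visit."""
    return add_months(last_visit_date, -1)


def index_date_for(record, lead_months: int = 5) -> dt.date:
    if record.is_case:
        return index_date_for_case(record.diagnosis_month, lead_months)
    return index_date_for_control(record.last_visit_date)


def age_at(birth_year: int, on: dt.date) -> float:
    """Age in years from year of birth (mid-year convention, July 1)."""
    return (on - dt.date(birth_year, 7, 1)).days / 365.25


@dataclass
class ObservationWindow:
    patient_id: str
    centre_id: str
    label: int
    index_date: dt.date
    window_start: dt.date
    tokens: list[str]
    icpc_counts: dict[str, int]
    age_years: float
    sex: str
    short_history: bool = False

    @property
    def all_oov(self) -> bool:
        return not self.tokens


@dataclass
class ExclusionTable:
    """Step table of the selection funnel: input = retained + exclusions."""

    n_input: int = 0
    n_retained: int = 0
    excluded: dict[str, int] = field(
        default_factory=lambda: {"age": 0, "history": 0, "text": 0}
    )
    excluded_ids: dict[str, list[str]] = field(
        default_factory=lambda: {"age": [], "history": [], "text": []}
    )

    def to_tsv(self, path: str | Path) -> None:
        rows = ["step\tn_remaining\tn_excluded\treason"]
        remaining = self.n_input
        rows.append(f"input\t{remaining}\t0\t-")
        for reason in ("age", "history", "text"):
            n = self.excluded[reason]
            remaining -= n
            rows.append(f"exclude_{reason}\t{remaining}\t{n}\t{reason}")
        rows.append(f"retained\t{self.n_retained}\t0\t-")
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def _window_has_text(record, index_date: dt.date, span_months: int) -> bool:
    start = add_months(index_date, -span_months)
    return any(
        start <= d < index_date and text.strip() for d, text in record.notes
    )


def select_patients(
    records,
    min_age: float = 40.0,
    min_history_months: int = 24,
    require_text: bool = True,
    lead_months: int = 5,
    span_months: int = 24,
    index_dates: dict[str, dt.date] | None = None,
) -> tuple[list, ExclusionTable]:
    """Apply the cohort filters at each patient's index date.

    Exclusion precedence is fixed (age, then history, then text) so the
    step table is deterministic; permuting the input permutes the output
    identically.  ``index_dates`` may supply precomputed per-patient
    index dates; otherwise they are derived from diagnosis month (cases)
    or last visit (controls).
    """
    table = ExclusionTable(n_input=len(records))
    kept = []
    for rec in records:
        if rec.sex not in ("female", "male") or rec.birth_year is None:
            raise ValueError(
                f"patient {rec.patient_id}: missing or invalid sex/birth_year"
            )
        idx = (
            index_dates[rec.patient_id]
            if index_dates is not None
            else index_date_for(rec, lead_months)
        )
        if age_at(rec.birth_year, idx) < min_age:
            table.excluded["age"] += 1
            table.excluded_ids["age"].append(rec.patient_id)
            continue
        earliest = rec.first_contact_date
        if earliest > add_months(idx, -min_history_months):
            table.excluded["history"] += 1
            table.excluded_ids["history"].append(rec.patient_id)
            continue
        if require_text and not _window_has_text(rec, idx, span_months):
            table.excluded["text"] += 1
            table.excluded_ids["text"].append(rec.patient_id)
            continue
        kept.append(rec)
    table.n_retained = len(kept)
    return kept, table


def build_window(
    record,
    index_date: dt.date,
    span_months: int = 24,
    catalogue: IcpcCatalogue = DEFAULT_CATALOGUE,
    codes: tuple[str, ...] | None = None,
) -> ObservationWindow:
    """Build the feature snapshot over ``[index - span_months, index)``.

    ``codes`` overrides which ICPC codes are tallied (defaults to the
    catalogue's full candidate list so downstream selection can choose).
    """
    start = add_months(index_date, -span_months)
    tokens: list[str] = []
    for d, text in record.notes:
        if start <= d < index_date:
            tokens.extend(normalize_text(text))
    tally_codes = codes if codes is not None else catalogue.candidates
    counts = {c: 0 for c in tally_codes}
    for d, code in record.episodes:
        if start <= d < index_date and code in counts:
            counts[code] += 1
    short = record.first_contact_date > start
    return ObservationWindow(
        patient_id=record.patient_id,
        centre_id=record.centre_id,
        label=int(record.is_case),
        index_date=index_date,
        window_start=start,
        tokens=tokens,
        icpc_counts=counts,
        age_years=age_at(record.birth_year, index_date),
        sex=record.sex,
        short_history=short,
    )


def write_windows_jsonl(windows, path: str | Path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for w in windows:
            fh.write(json.dumps({
                "patient_id": w.patient_id,
                "centre_id": w.centre_id,
                "label": w.label,
                "index_date": w.index_date.isoformat(),
                "window_start": w.window_start.isoformat(),
                "tokens": w.tokens,
                "icpc_counts": w.icpc_counts,
                "age_years": w.age_years,
                "sex": w.sex,
            }, ensure_ascii=False) + "\n")


def read_windows_jsonl(path: str | Path) -> list[ObservationWindow]:
    import json

    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            o = json.loads(line)
            out.append(ObservationWindow(
                patient_id=o["patient_id"],
                centre_id=o["centre_id"],
                label=o["label"],
                index_date=dt.date.fromisoformat(o["index_date"]),
                window_start=dt.date.fromisoformat(o["window_start"]),
                tokens=o["tokens"],
                icpc_counts=o["icpc_counts"],
                age_years=o["age_years"],
                sex=o["sex"],
            ))
    return out


def build_cohort_windows(
    records,
    lead_months: int = 5,
    span_months: int = 24,
    min_age: float = 40.0,
    min_history_months: int = 24,
    require_text: bool = True,
    catalogue: IcpcCatalogue = DEFAULT_CATALOGUE,
) -> tuple[list[ObservationWindow], ExclusionTable]:
    """Selection + windowing in one pass (the cohort stage of the pipeline)."""
    kept, table = select_patients(
        records,
        min_age=min_age,
        min_history_months=min_history_months,
        require_text=require_text,
        lead_months=lead_months,
        span_months=span_months,
    )
    windows = [
        build_window(rec, index_date_for(rec, lead_months), span_months, catalogue)
        for rec in kept
    ]
    return windows, table
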