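"""Longitudinal GP patient records and their JSONL interchange format.

One patient per JSON line:

    {"patient_id": "...", "centre_id": "...", "sex": "female"|"male",
     "birth_year": 1950,
     "notes": [["YYYY-MM-DD", "free text"], ...],
     "episodes": [["YYYY-MM-DD", "ICPC"], ...],
     "diagnosis_month": "YYYY-MM" | null}

Notes and episodes are kept sorted ascending by date; ``last_visit_date``
is the latest contact of any kind (note or coded episode).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

SEXES = ("female", "male")


@dataclass
class PatientRecord:
    patient_id: str
    centre_id: str
    sex: str
    birth_year: int
    notes: list[tuple[dt.date, str]] = field(default_factory=list)
    episodes: list[tuple[dt.date, str]] = field(default_factory=list)
    diagnosis_month: str | None = None  # "YYYY-MM" for cases, None otherwise

    def __post_init__(self) -> None:
        self.notes.sort(key=lambda x: x[0])
        self.episodes.sort(key=lambda x: x[0])

    @property
    def is_case(self) -> bool:
        return self.diagnosis_month is not None

    @property
    def last_visit_date(self) -> dt.date:
        dates = [d for d, _ in self.notes] + [d for d, _ in self.episodes]
        if not dates:
            raise ValueError(f"patient {self.patient_id} has no contacts")
        return max(dates)

    @property
    def first_contact_date(self) -> dt.date:
        dates = [d for d, _ in self.notes] + [d for d, _ in self.episodes]
        if not dates:
            raise ValueError(f"patient {self.patient_id} has no contacts")
        return min(dates)

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "centre_id": self.centre_id,
                "sex": self.sex,
                "birth_year": self.birth_year,
                "notes": [[d.isoformat(), t] for d, t in self.notes],
                "episodes": [[d.isoformat(), c] for d, c in self.episodes],
                "diagnosis_month": self.diagnosis_month,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "PatientRecord":
        obj = json.loads(line)
        return cls(
            patient_id=obj["patient_id"],
            centre_id=obj["centre_id"],
            sex=obj["sex"],
            birth_year=obj["birth_year"],
            notes=[(dt.date.fromisoformat(d), t) for d, t in obj["notes"]],
            episodes=[(dt.date.fromisoformat(d), c) for d, c in obj["episodes"]],
            diagnosis_month=obj.get("diagnosis_month"),
        )


def write_jsonl(records: Iterable[PatientRecord], path: str | Path | IO[str]) -> None:
    if hasattr(path, "write"):
        for rec in records:
            path.write(rec.to_json() + "\n")
        return
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_jsonl(path: str | Path) -> Iterator[PatientRecord]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield PatientRecord.from_json(line)
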