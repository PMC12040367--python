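import datetime as dt

import numpy as np
import pytest

from lungrisk.cohort import ObservationWindow
from lungrisk.records import PatientRecord


def make_record(
    pid="p1",
    centre="centre0",
    sex="female",
    birth_year=1950,
    note_dates=("2017-01-10", "2019-06-01", "2020-11-20"),
    diagnosis_month=None,
    episodes=(),
):
    return PatientRecord(
        patient_id=pid,
        centre_id=centre,
        sex=sex,
        birth_year=birth_year,
        notes=[(dt.date.fromisoformat(d), f"controle bezoek {i}")
               for i, d in enumerate(note_dates)],
        episodes=[(dt.date.fromisoformat(d), c) for d, c in episodes],
        diagnosis_month=diagnosis_month,
    )


def make_windows(n=300, prevalence=0.2, vocab=40, doc_len=30,
                 n_centres=3, signal_boost=6, seed=0):
    """Synthetic observation windows with a direct token-level signal,
    bypassing the full record generator (fast path for pipeline tests)."""
    rng = np.random.default_rng(seed)
    words = [f"t{i}" for i in range(vocab)]
    signal = ["sig_a", "sig_b", "sig_c"]
    out = []
    for i in range(n):
        label = int(rng.random() < prevalence)
        toks = list(rng.choice(words, size=doc_len))
        n_sig = rng.poisson(signal_boost if label else 1.0)
        toks += list(rng.choice(signal, size=n_sig))
        out.append(ObservationWindow(
            patient_id=f"w{i}",
            centre_id=f"centre{i % n_centres}",
            label=label,
            index_date=dt.date(2020, 6, 15),
            window_start=dt.date(2018, 6, 15),
            tokens=toks,
            icpc_counts={"B02": int(rng.poisson(0.2 + 0.5 * label)),
                         "P17": int(rng.poisson(0.3))},
            age_years=float(rng.integers(45, 90)),
            sex="female" if rng.random() < 0.5 else "male",
        ))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
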