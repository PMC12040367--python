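"""Multi-centre synthetic GP cohorts with a planted pre-diagnostic signal.

The generator emulates the statistical structure a lung-cancer
case-finding analysis assumes about routine primary-care data:

* ~0.5% outcome prevalence among patients aged >= 40, with cases older
  than controls (band weights follow the reference cohort's age table);
* month-granularity diagnosis dates and 32-60 months of history per
  patient, so a 24-month window plus a 2-6 month lead always fits;
* free-text notes modelled as bags of tokens from a Zipf-distributed
  background vocabulary, with a small set of symptom ("signal") tokens
  whose per-note emission rate is multiplied by ``signal_gain`` during
  the pre-diagnostic year of cases;
* ICPC-coded episodes drawn per code at a base rate per patient-year,
  multiplied for cases in the pre-diagnostic year;
* four centres whose background token distributions are
  Dirichlet-perturbed copies of a shared distribution, plus a disjoint
  per-centre "style token" subset — a controllable distribution shift
  that makes leave-centre-out validation degrade relative to internal
  validation.

Everything is driven by one seeded generator stream, so a config + seed
pair reproduces the cohort byte for byte.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .records import PatientRecord

DEFAULT_SIGNAL_TOKENS = (
    "hoesten",
    "vermoeidheid",
    "afvallen",
    "kortademig",
    "pijnborst",
    "bloedophoesten",
)

# Base ICPC episode rates per patient-year; the selected five codes get a
# case multiplier in the pre-diagnostic year, the ten candidate-only
# codes stay at background (pure noise for the variable selection).
DEFAULT_ICPC_BASE_RATES: dict[str, float] = {
    "B02": 0.02, "D01": 0.04, "P17": 0.06, "T03": 0.02, "T08": 0.03,
    "A04": 0.15, "B80": 0.03, "B82": 0.03, "D87": 0.08, "K94": 0.01,
    "L04": 0.07, "R02": 0.06, "R05": 0.30, "R24": 0.005, "R81": 0.03,
}
DEFAULT_ICPC_CASE_MULTIPLIER: dict[str, float] = {
    "B02": 3.0, "D01": 2.0, "P17": 2.5, "T03": 3.0, "T08": 3.5,
}

# Age-band weights for 40-59 / 60-69 / 70-79 / >=80, per outcome class
# (cases skew older, as in routine-care lung-cancer cohorts).
CONTROL_AGE_WEIGHTS = (0.542, 0.213, 0.148, 0.097)
CASE_AGE_WEIGHTS = (0.204, 0.341, 0.319, 0.136)
AGE_BANDS = ((40, 59), (60, 69), (70, 79), (80, 94))

_END_ANCHOR = (2020, 12)  # latest possible history month (year, month)


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    prevalence: float = 0.005
    n_centres: int = 4
    centre_weights: tuple[float, ...] | None = None
    centre_prevalence_multipliers: tuple[float, ...] | None = (
        0.6, 0.9, 1.1, 1.4
    )  # relative outcome rates per centre (rescaled to keep the overall
       # prevalence); None = homogeneous centres
    vocab_size: int = 800
    note_rate: float = 0.4            # mean notes per patient-month (cases)
    control_note_rate: float | None = None  # defaults to note_rate
    note_length_mean: float = 8.0     # background tokens per note
    signal_tokens: tuple[str, ...] = DEFAULT_SIGNAL_TOKENS
    signal_base_rate: float = 0.5     # expected signal tokens per note, background
    signal_gain: float = 3.0          # step multiplier in the signal window
    signal_window_months: int = 12    # months before diagnosis with elevated rate
    icpc_base_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ICPC_BASE_RATES)
    )
    icpc_case_multiplier: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ICPC_CASE_MULTIPLIER)
    )
    centre_shift: float = 0.3         # Dirichlet perturbation scale (0 = none)
    style_tokens_per_centre: int = 5
    style_token_rate: float = 0.5     # style tokens per note when shift > 0
    signal_dialect_rate: float = 0.3  # share of signal mentions written in a
                                      # centre-local variant (when shift > 0)
    centre_signal_rate_multipliers: tuple[float, ...] | None = (
        0.6, 0.9, 1.1, 1.4
    )  # per-centre symptom-documentation intensity (scales the signal-token
       # emission rate for cases and controls alike); None = homogeneous
    empty_note_prob: float = 0.0      # chance a note is emitted empty
    age_weights_controls: tuple[float, ...] = CONTROL_AGE_WEIGHTS
    age_weights_cases: tuple[float, ...] = CASE_AGE_WEIGHTS
    female_rate_controls: float = 0.525
    female_rate_cases: float = 0.461
    history_span_months: tuple[int, int] = (32, 60)
    seed: int = 0

    def as_null(self) -> "SimulationConfig":
        """A copy with every case/control difference removed: unit signal
        gain, unit ICPC multipliers, identical age and sex distributions.
        Labels are then independent of all generated features."""
        import dataclasses

        return dataclasses.replace(
            self,
            signal_gain=1.0,
            icpc_case_multiplier={},
            age_weights_cases=self.age_weights_controls,
            female_rate_cases=self.female_rate_controls,
            centre_prevalence_multipliers=None,
        )

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not 0.0 <= self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in [0, 1)")
        if self.n_centres <= 0:
            raise ConfigurationError("n_centres must be positive")
        w = self.resolved_centre_weights()
        if len(w) != self.n_centres:
            raise ConfigurationError("centre_weights length != n_centres")
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigurationError("centre_weights must be a probability vector")
        for fname in ("centre_prevalence_multipliers",
                      "centre_signal_rate_multipliers"):
            m = getattr(self, fname)
            if m is not None and (
                len(m) != self.n_centres or any(x <= 0 for x in m)
            ):
                raise ConfigurationError(
                    f"{fname} must be positive and match n_centres"
                )
        if self.vocab_size <= 0 or not self.signal_tokens:
            raise ConfigurationError("vocab_size/signal_tokens must be nonempty")
        for name in ("note_rate", "note_length_mean", "signal_base_rate",
                     "style_token_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.signal_gain < 1.0:
            raise ConfigurationError("signal_gain must be >= 1")
        if self.centre_shift < 0:
            raise ConfigurationError("centre_shift must be >= 0")
        for code, rate in self.icpc_base_rates.items():
            if rate < 0:
                raise ConfigurationError(f"icpc_base_rates[{code}] must be >= 0")
        for code, mult in self.icpc_case_multiplier.items():
            if mult < 0:
                raise ConfigurationError(
                    f"icpc_case_multiplier[{code}] must be >= 0"
                )
        for name in ("female_rate_controls", "female_rate_cases"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        lo, hi = self.history_span_months
        if lo < 26 or hi < lo:
            raise ConfigurationError(
                "history_span_months must satisfy 26 <= lo <= hi"
            )
        if not 0.0 <= self.empty_note_prob <= 1.0:
            raise ConfigurationError("empty_note_prob must be in [0, 1]")

    def resolved_centre_weights(self) -> tuple[float, ...]:
        if self.centre_weights is not None:
            return tuple(self.centre_weights)
        return tuple(1.0 / self.n_centres for _ in range(self.n_centres))

    def gain_at(self, months_to_diagnosis: int | None) -> float:
        """Signal-token enrichment as a function of months to diagnosis.

        Step profile: ``signal_gain`` within ``signal_window_months``
        before diagnosis, 1 elsewhere (and for controls).  >= 1 always,
        non-increasing as distance to diagnosis grows.
        """
        if months_to_diagnosis is None:
            return 1.0
        if 0 <= months_to_diagnosis < self.signal_window_months:
            return self.signal_gain
        return 1.0


@dataclass
class GroundTruth:
    """Per-patient oracle for recovery experiments."""

    labels: dict[str, int]
    diagnosis_months: dict[str, str | None]
    signal_token_counts: dict[str, int]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["patient_id\tlabel\tdiagnosis_month\tsignal_token_count"]
        for pid in self.labels:
            dm = self.diagnosis_months[pid] or ""
            lines.append(
                f"{pid}\t{self.labels[pid]}\t{dm}\t{self.signal_token_counts[pid]}"
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class CentreStyle:
    """A centre's token-emission model: perturbed unigram, style tokens,
    and local spelling variants of the shared signal tokens."""

    unigram_cdf: np.ndarray        # cumulative probs over background tokens
    background_tokens: list[str]
    style_tokens: list[str]
    signal_variants: list[str]     # centre-local forms, parallel to
                                   # config.signal_tokens (empty = none)
    signal_rate_multiplier: float = 1.0  # documentation-intensity scale


@dataclass
class PatientState:
    centre: CentreStyle
    is_case: bool


def _month_to_date_parts(month_index: int) -> tuple[int, int]:
    """Month index counted in absolute months (year*12 + month-1)."""
    return divmod(month_index, 12)[0], divmod(month_index, 12)[1] + 1


def _ym_index(year: int, month: int) -> int:
    return year * 12 + (month - 1)


def build_centre_styles(config: SimulationConfig, rng: np.random.Generator
                        ) -> list[CentreStyle]:
    n_style = config.style_tokens_per_centre if config.centre_shift > 0 else 0
    background = [f"w{i:04d}" for i in range(config.vocab_size)]
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    base = 1.0 / (ranks + 2.0)  # Zipf-like background frequencies
    base /= base.sum()
    styles = []
    for c in range(config.n_centres):
        if config.centre_shift > 0:
            alpha = np.maximum(base / config.centre_shift, 1e-6)
            probs = rng.dirichlet(alpha)
        else:
            probs = base
        style_tokens = [f"style_c{c}_{k}" for k in range(n_style)]
        variants = (
            [f"{t}c{c}" for t in config.signal_tokens]
            if config.centre_shift > 0 and config.signal_dialect_rate > 0
            else []
        )
        mult = (
            config.centre_signal_rate_multipliers[c]
            if config.centre_signal_rate_multipliers is not None
            else 1.0
        )
        styles.append(
            CentreStyle(
                unigram_cdf=np.cumsum(probs),
                background_tokens=background,
                style_tokens=style_tokens,
                signal_variants=variants,
                signal_rate_multiplier=mult,
            )
        )
    return styles


def generate_note(
    state: PatientState,
    months_to_diagnosis: int | None,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Emit one note as a bag of tokens.

    Background tokens ~ Poisson(note_length_mean) from the centre's
    perturbed unigram; signal tokens ~ Poisson(base * gain(m)), so a
    case's expected signal-token count is exactly the background rate
    times the gain; style tokens ~ Poisson(style rate) from the
    centre-specific disjoint subset.
    """
    if not state.centre.background_tokens:
        raise ConfigurationError("vocab_size must be nonempty")
    if config.empty_note_prob > 0 and rng.random() < config.empty_note_prob:
        return []
    n_bg = rng.poisson(config.note_length_mean)
    tokens: list[str] = []
    if n_bg:
        u = rng.random(n_bg)
        idx = np.searchsorted(state.centre.unigram_cdf, u)
        tokens.extend(state.centre.background_tokens[i] for i in idx)
    gain = config.gain_at(months_to_diagnosis if state.is_case else None)
    n_sig = rng.poisson(
        config.signal_base_rate * gain * state.centre.signal_rate_multiplier
    )
    if n_sig:
        sig_idx = rng.integers(0, len(config.signal_tokens), size=n_sig)
        variants = state.centre.signal_variants
        for i in sig_idx:
            if variants and rng.random() < config.signal_dialect_rate:
                tokens.append(variants[i])
            else:
                tokens.append(config.signal_tokens[i])
    if state.centre.style_tokens and config.style_token_rate > 0:
        n_sty = rng.poisson(config.style_token_rate)
        if n_sty:
            sty_idx = rng.integers(0, len(state.centre.style_tokens), size=n_sty)
            tokens.extend(state.centre.style_tokens[i] for i in sty_idx)
    if len(tokens) > 1:
        tokens = [tokens[i] for i in rng.permutation(len(tokens))]
    return tokens


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a full multi-centre cohort; reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    styles = build_centre_styles(config, rng)
    weights = np.asarray(config.resolved_centre_weights())

    centres = rng.choice(config.n_centres, size=n, p=weights)
    if config.centre_prevalence_multipliers is not None:
        mult = np.asarray(config.centre_prevalence_multipliers, dtype=float)
        mult = mult / float(weights @ mult)  # keep the overall prevalence
        p_i = np.clip(config.prevalence * mult[centres], 0.0, 1.0)
    else:
        p_i = np.full(n, config.prevalence)
    labels = (rng.random(n) < p_i).astype(int)
    spans = rng.integers(
        config.history_span_months[0], config.history_span_months[1] + 1, size=n
    )
    end_jitter = rng.integers(0, 7, size=n)

    codes = sorted(config.icpc_base_rates)
    base_rates = np.array([config.icpc_base_rates[c] for c in codes])
    case_mult = np.array(
        [config.icpc_case_multiplier.get(c, 1.0) for c in codes]
    )

    control_rate = (
        config.note_rate
        if config.control_note_rate is None
        else config.control_note_rate
    )

    records: list[PatientRecord] = []
    truth_labels: dict[str, int] = {}
    truth_diag: dict[str, str | None] = {}
    truth_sig: dict[str, int] = {}
    anchor_idx = _ym_index(*_END_ANCHOR)
    sigset = set(config.signal_tokens)
    for st in styles:
        sigset.update(st.signal_variants)

    for i in range(n):
        pid = f"p{i:06d}"
        is_case = bool(labels[i])
        centre = styles[centres[i]]
        state = PatientState(centre=centre, is_case=is_case)
        end_idx = anchor_idx - int(end_jitter[i])
        span = int(spans[i])
        start_idx = end_idx - (span - 1)

        if is_case:
            # diagnosis in one of the last 3 history months, so the
            # 24-month window at a 2-6 month lead always fits
            diag_idx = end_idx - int(rng.integers(0, 3))
            dy, dm = _month_to_date_parts(diag_idx)
            diagnosis_month = f"{dy:04d}-{dm:02d}"
        else:
            diag_idx = None
            diagnosis_month = None

        band = rng.choice(
            4,
            p=np.asarray(
                config.age_weights_cases if is_case else config.age_weights_controls
            ),
        )
        lo, hi = AGE_BANDS[band]
        age = int(rng.integers(lo, hi + 1))
        end_year = _month_to_date_parts(end_idx)[0]
        birth_year = end_year - age
        female_rate = (
            config.female_rate_cases if is_case else config.female_rate_controls
        )
        sex = "female" if rng.random() < female_rate else "male"

        rate = config.note_rate if is_case else control_rate
        n_notes_per_month = rng.poisson(rate, size=span)
        # guarantee one early and one late contact so history span and
        # last-visit anchoring are well defined
        if n_notes_per_month[0] == 0:
            n_notes_per_month[0] = 1
        if n_notes_per_month[-1] == 0:
            n_notes_per_month[-1] = 1

        notes: list[tuple[dt.date, str]] = []
        sig_count = 0
        for m_off in range(span):
            k = int(n_notes_per_month[m_off])
            if k == 0:
                continue
            month_idx = start_idx + m_off
            y, mo = _month_to_date_parts(month_idx)
            ndays = calendar.monthrange(y, mo)[1]
            mtd = diag_idx - month_idx if diag_idx is not None else None
            for _ in range(k):
                day = int(rng.integers(1, ndays + 1))
                toks = generate_note(state, mtd, config, rng)
                sig_count += sum(1 for t in toks if t in sigset)
                notes.append((dt.date(y, mo, day), " ".join(toks)))

        episodes: list[tuple[dt.date, str]] = []
        lam = np.tile(base_rates[:, None] / 12.0, (1, span))
        if is_case:
            pre = np.array(
                [
                    0 <= (diag_idx - (start_idx + m)) < 12
                    for m in range(span)
                ]
            )
            lam[:, pre] *= case_mult[:, None]
        counts = rng.poisson(lam)
        for ci, code in enumerate(codes):
            for m_off in np.nonzero(counts[ci])[0]:
                month_idx = start_idx + int(m_off)
                y, mo = _month_to_date_parts(month_idx)
                ndays = calendar.monthrange(y, mo)[1]
                for _ in range(int(counts[ci, m_off])):
                    day = int(rng.integers(1, ndays + 1))
                    episodes.append((dt.date(y, mo, day), code))

        records.append(
            PatientRecord(
                patient_id=pid,
                centre_id=f"centre{int(centres[i])}",
                sex=sex,
                birth_year=birth_year,
                notes=notes,
                episodes=episodes,
                diagnosis_month=diagnosis_month,
            )
        )
        truth_labels[pid] = int(is_case)
        truth_diag[pid] = diagnosis_month
        truth_sig[pid] = sig_count

    truth = GroundTruth(
        labels=truth_labels,
        diagnosis_months=truth_diag,
        signal_token_counts=truth_sig,
    )
    return records, truth
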