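"""Synthetic cohort generator: reproducibility, planted signal, config errors."""

import io

import numpy as np
import pytest

from lungrisk.records import write_jsonl
from lungrisk.synthetic import (
    CentreStyle,
    ConfigurationError,
    PatientState,
    SimulationConfig,
    build_centre_styles,
    generate_cohort,
    generate_note,
)

FAST = dict(vocab_size=50, note_rate=0.05, note_length_mean=3.0,
            history_span_months=(26, 30), style_tokens_per_centre=2)


class TestGenerateCohort:
    def test_case_count_is_binomial(self):
        # single draw stays within the essentially-sure binomial range,
        # and the mean over 200 seeds matches n*p = 5
        counts = []
        for seed in range(200):
            cfg = SimulationConfig(n_patients=1000, prevalence=0.005,
                                   seed=seed, **FAST)
            _, truth = generate_cohort(cfg)
            counts.append(sum(truth.labels.values()))
        assert all(0 <= c <= 15 for c in counts)
        assert 4.0 <= np.mean(counts) <= 6.0

    def test_seeded_output_byte_identical(self):
        cfg = SimulationConfig(n_patients=50, prevalence=0.05, seed=7, **FAST)
        outs = []
        for _ in range(2):
            recs, _ = generate_cohort(cfg)
            buf = io.StringIO()
            write_jsonl(recs, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_zero_prevalence_means_no_cases(self):
        cfg = SimulationConfig(n_patients=100, prevalence=0.0, seed=1, **FAST)
        recs, truth = generate_cohort(cfg)
        assert all(v == 0 for v in truth.labels.values())
        assert all(r.diagnosis_month is None for r in recs)

    def test_label_iff_diagnosis_month(self):
        cfg = SimulationConfig(n_patients=300, prevalence=0.1, seed=3, **FAST)
        recs, truth = generate_cohort(cfg)
        for rec in recs:
            assert truth.labels[rec.patient_id] == int(
                rec.diagnosis_month is not None
            )

    def test_every_patient_has_notes_and_history(self):
        cfg = SimulationConfig(n_patients=100, prevalence=0.05, seed=2, **FAST)
        recs, _ = generate_cohort(cfg)
        for rec in recs:
            assert rec.notes
            span_days = (rec.last_visit_date - rec.first_contact_date).days
            assert span_days >= 24 * 28  # at least ~24 months of record

    def test_centres_differ_in_background_frequencies(self):
        cfg = SimulationConfig(n_patients=1, centre_shift=0.5, seed=0)
        styles = build_centre_styles(cfg, np.random.default_rng(0))
        pmfs = [np.diff(np.concatenate([[0], s.unigram_cdf])) for s in styles]
        assert np.abs(pmfs[0] - pmfs[1]).sum() > 0.05

    @pytest.mark.parametrize(
        "bad",
        [
            dict(prevalence=-0.1),
            dict(n_centres=2),  # default weights fine, but multipliers are 4
            dict(centre_weights=(0.5, 0.2, 0.2, 0.2)),
            dict(note_rate=-1.0),
            dict(signal_gain=0.5),
            dict(icpc_base_rates={"R05": -0.1}),
            dict(history_span_months=(10, 20)),
        ],
    )
    def test_invalid_config_raises_naming_field(self, bad):
        cfg = SimulationConfig(n_patients=10, **bad)
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestSignalGain:
    def test_gain_profile_step(self):
        cfg = SimulationConfig(signal_gain=10.0, signal_window_months=12)
        assert cfg.gain_at(0) == 10.0
        assert cfg.gain_at(11) == 10.0
        assert cfg.gain_at(12) == 1.0
        assert cfg.gain_at(-3) == 1.0  # after diagnosis
        assert cfg.gain_at(None) == 1.0
        # >= 1 everywhere, non-increasing with distance to diagnosis
        gains = [cfg.gain_at(m) for m in range(0, 40)]
        assert all(g >= 1 for g in gains)
        assert all(a >= b for a, b in zip(gains, gains[1:]))

    def _count_signal(self, config, months_to_diagnosis, n_notes, seed=0):
        rng = np.random.default_rng(seed)
        styles = build_centre_styles(config, rng)
        state = PatientState(centre=styles[0], is_case=True)
        sigset = set(config.signal_tokens) | set(styles[0].signal_variants)
        total = 0
        for _ in range(n_notes):
            toks = generate_note(state, months_to_diagnosis, config, rng)
            total += sum(1 for t in toks if t in sigset)
        return total

    def test_elevated_window_ratio_matches_gain(self):
        # Poisson oracle: mean signal count at m=3 (gain g) over m=30
        # (background) should be ~g, within 3 standard errors
        g = 10.0
        cfg = SimulationConfig(signal_gain=g, signal_base_rate=0.5,
                               centre_signal_rate_multipliers=None)
        n = 1000
        near = self._count_signal(cfg, 3, n)
        far = self._count_signal(cfg, 30, n, seed=1)
        lam = cfg.signal_base_rate
        se_ratio = 3 * np.sqrt(g * lam * n + g**2 * lam * n) / (lam * n)
        assert abs(near / max(far, 1) - g) < se_ratio

    def test_unit_gain_identical_distributions(self):
        cfg = SimulationConfig(signal_gain=1.0,
                               centre_signal_rate_multipliers=None)
        n = 2000
        a = self._count_signal(cfg, 3, n)
        b = self._count_signal(cfg, 30, n, seed=1)
        lam = cfg.signal_base_rate * n
        assert abs(a - b) < 3 * np.sqrt(2 * lam)

    def test_empty_vocabulary_raises(self):
        cfg = SimulationConfig()
        style = CentreStyle(np.array([1.0]), [], [], [])
        with pytest.raises(ConfigurationError):
            generate_note(PatientState(style, False), None, cfg,
                          np.random.default_rng(0))


class TestCentreHeterogeneity:
    def test_prevalence_multipliers_shift_centre_rates(self):
        cfg = SimulationConfig(
            n_patients=20000, prevalence=0.05, seed=5,
            centre_prevalence_multipliers=(0.4, 0.8, 1.2, 1.6), **FAST
        )
        recs, truth = generate_cohort(cfg)
        rates = {}
        for rec in recs:
            rates.setdefault(rec.centre_id, []).append(
                truth.labels[rec.patient_id]
            )
        means = [np.mean(rates[c]) for c in sorted(rates)]
        assert means[0] < means[-1]
        # overall prevalence preserved
        assert abs(np.mean(sum(rates.values(), [])) - 0.05) < 0.01

    def test_null_config_removes_class_differences(self):
        cfg = SimulationConfig(n_patients=10).as_null()
        assert cfg.signal_gain == 1.0
        assert cfg.icpc_case_multiplier == {}
        assert cfg.age_weights_cases == cfg.age_weights_controls
        assert cfg.female_rate_cases == cfg.female_rate_controls
        assert cfg.centre_prevalence_multipliers is None
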