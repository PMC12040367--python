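"""End-to-end runs: simulate/load -> cohort -> embed -> fit -> evaluate.

Three entry points mirror the study design:

* :func:`run_internal` — outcome-stratified 60/20/20 split, phrase +
  SGNS embedding fitted on the training split only, AIC code selection,
  TO and TC logistic fits, full evaluation on the test split;
* :func:`run_external` / :func:`leave_centre_out` — for each centre,
  the whole pipeline is refitted with that centre excluded and its
  patients scored; held-out predictions are stacked into one set whose
  metrics are the overall external performance;
* :func:`run_leadtime_sweep` — internal validation repeated for lead
  times of 2-6 months with a shared seed.

Every run can write its artifacts plus a :class:`RunManifest` (config
snapshot, seeds, row counts, output digests) so deterministic reruns
are checkable by digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import (
    DEFAULT_CATALOGUE,
    ExclusionTable,
    IcpcCatalogue,
    ObservationWindow,
    build_cohort_windows,
)
from .evaluation import (
    DEFAULT_PPV_TARGETS,
    MetricReport,
    PredictionSet,
    auroc,
    build_metric_report,
    concatenate,
    stratified_split,
)
from .logistic import FeatureBlock, RiskModel, backward_aic, fit_logistic, predict_risk
from .phrases import PhraseVocabulary, learn_phrases
from .sgns import EmbeddingModel, SGNSParams, embed_document, train_sgns


@dataclass
class PipelineConfig:
    # cohort
    lead_months: int = 5
    span_months: int = 24
    min_age: float = 40.0
    min_history_months: int = 24
    require_text: bool = True
    # phrase detection
    phrase_min_count: int = 5
    phrase_discount: float = 5.0
    phrase_threshold: float = 10.0
    phrase_passes: int = 1
    # embedding
    embedding_dim: int = 100
    embedding_window: int = 5
    embedding_negatives: int = 5
    embedding_subsample: float = 1e-3
    embedding_epochs: int = 5
    embedding_weighting: str = "uniform"
    # models
    ridge_penalty: float = 1.0
    aic_with_embedding: bool = False
    tune_ridge_grid: tuple[float, ...] | None = None
    tuning_criterion: str = "auroc"
    # evaluation
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    bootstrap_B: int = 1000
    ppv_targets: tuple[float, ...] = DEFAULT_PPV_TARGETS
    with_operating_cis: bool = False
    # reproducibility
    seed: int = 0

    def sgns_params(self) -> SGNSParams:
        return SGNSParams(
            dim=self.embedding_dim,
            window=self.embedding_window,
            negatives=self.embedding_negatives,
            subsample=self.embedding_subsample,
            epochs=self.embedding_epochs,
            seed=self.seed,
        )


@dataclass
class TrainedModels:
    embedding: EmbeddingModel
    selected_codes: list[str]
    to_model: RiskModel
    tc_model: RiskModel


@dataclass
class RunManifest:
    config: dict
    seed: int
    started: str
    finished: str = ""
    stage_counts: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.output_digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _embedding_features(
    model: EmbeddingModel, windows: Sequence[ObservationWindow], weighting: str
) -> np.ndarray:
    return np.vstack(
        [embed_document(model, w.tokens, weighting=weighting).values for w in windows]
    )


def _coded_features(
    windows: Sequence[ObservationWindow], codes: Sequence[str]
) -> np.ndarray:
    rows = [
        [w.age_years, 1.0 if w.sex == "female" else 0.0]
        + [float(w.icpc_counts.get(c, 0)) for c in codes]
        for w in windows
    ]
    return np.asarray(rows, dtype=float)


def _labels(windows: Sequence[ObservationWindow]) -> np.ndarray:
    return np.array([w.label for w in windows], dtype=int)


def fit_pipeline(
    train: Sequence[ObservationWindow],
    config: PipelineConfig,
    catalogue: IcpcCatalogue = DEFAULT_CATALOGUE,
) -> TrainedModels:
    """Fit vocabulary, embedding, code selection, and both risk models
    on the training windows only (everything downstream is frozen)."""
    corpus = [w.tokens for w in train]
    vocab = learn_phrases(
        corpus,
        min_count=config.phrase_min_count,
        discount=config.phrase_discount,
        threshold=config.phrase_threshold,
        passes=config.phrase_passes,
    )
    embedding = train_sgns(corpus, vocab, config.sgns_params())

    y = _labels(train)
    emb = _embedding_features(embedding, train, config.embedding_weighting)
    candidates = list(catalogue.candidates)
    cand_matrix = np.asarray(
        [[float(w.icpc_counts.get(c, 0)) for c in candidates] for w in train]
    )
    base_cols = ["age", "sex_female"]
    base_matrix = _coded_features(train, [])  # age + sex only
    if config.aic_with_embedding:
        base = FeatureBlock(
            np.column_stack([base_matrix, emb]),
            tuple(base_cols + [f"e{i}" for i in range(emb.shape[1])]),
        )
    else:
        base = FeatureBlock(base_matrix, tuple(base_cols))
    selected = backward_aic(candidates, cand_matrix, y, base=base)

    emb_cols = tuple(f"e{i}" for i in range(emb.shape[1]))
    to_block = FeatureBlock(emb, emb_cols)
    to_model = fit_logistic(
        to_block, y, penalty=config.ridge_penalty, variant="TO"
    )
    tc_matrix = np.column_stack(
        [emb, _coded_features(train, selected)]
    )
    tc_cols = emb_cols + ("age", "sex_female") + tuple(selected)
    tc_block = FeatureBlock(tc_matrix, tc_cols)
    tc_model = fit_logistic(
        tc_block, y, penalty=config.ridge_penalty, variant="TC"
    )
    return TrainedModels(embedding, selected, to_model, tc_model)


def predict_windows(
    models: TrainedModels,
    windows: Sequence[ObservationWindow],
    config: PipelineConfig,
) -> dict[str, PredictionSet]:
    """Score windows with the frozen TO and TC models."""
    emb = _embedding_features(models.embedding, windows, config.embedding_weighting)
    emb_cols = tuple(f"e{i}" for i in range(emb.shape[1]))
    to_scores = predict_risk(models.to_model, FeatureBlock(emb, emb_cols))
    tc_matrix = np.column_stack(
        [emb, _coded_features(windows, models.selected_codes)]
    )
    tc_cols = emb_cols + ("age", "sex_female") + tuple(models.selected_codes)
    tc_scores = predict_risk(models.tc_model, FeatureBlock(tc_matrix, tc_cols))
    labels = _labels(windows)
    centres = np.array([w.centre_id for w in windows])
    pids = np.array([w.patient_id for w in windows])
    return {
        "TO": PredictionSet(to_scores, labels, centres, pids),
        "TC": PredictionSet(tc_scores, labels, centres, pids),
    }


@dataclass
class InternalResult:
    reports: dict[str, MetricReport]
    predictions: dict[str, PredictionSet]
    selected_codes: list[str]
    exclusion_table: ExclusionTable
    split_sizes: dict[str, int]
    manifest: RunManifest


def _manifest_start(config: PipelineConfig) -> RunManifest:
    return RunManifest(
        config=dataclasses.asdict(config),
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def run_internal(
    records,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> InternalResult:
    """Internal validation: split, fit on train, evaluate on test."""
    manifest = _manifest_start(config)
    windows, excl = build_cohort_windows(
        records,
        lead_months=config.lead_months,
        span_months=config.span_months,
        min_age=config.min_age,
        min_history_months=config.min_history_months,
        require_text=config.require_text,
    )
    manifest.stage_counts["records_in"] = len(records)
    manifest.stage_counts["windows"] = len(windows)
    _log(
        f"[cohort] {len(records)} records -> {len(windows)} windows "
        f"(excluded: {excl.excluded})"
    )

    y = _labels(windows)
    tr, tu, te = stratified_split(y, config.split_fractions, seed=config.seed)
    train = [windows[i] for i in tr]
    tune = [windows[i] for i in tu]
    test = [windows[i] for i in te]
    manifest.stage_counts.update(
        {"train": len(train), "tune": len(tune), "test": len(test)}
    )

    models = fit_pipeline(train, config)
    if config.tune_ridge_grid:
        models = _tune_ridge(models, train, tune, config)
    _log(f"[fit] selected ICPC codes: {models.selected_codes}")

    preds = predict_windows(models, test, config)
    reports = {
        name: build_metric_report(
            ps,
            name=f"internal-{name}",
            B=config.bootstrap_B,
            seed=config.seed,
            ppv_targets=config.ppv_targets,
            with_operating_cis=config.with_operating_cis,
        )
        for name, ps in preds.items()
    }
    for name, rep in reports.items():
        _log(f"[evaluate] {name}: AUROC={rep.auroc[0]:.4f}")

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    result = InternalResult(
        reports=reports,
        predictions=preds,
        selected_codes=models.selected_codes,
        exclusion_table=excl,
        split_sizes={"train": len(train), "tune": len(tune), "test": len(test)},
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        excl.to_tsv(out / "exclusion_steps.tsv")
        manifest.add_output(out / "exclusion_steps.tsv")
        for name, rep in reports.items():
            path = out / f"internal_{name}.json"
            path.write_text(json.dumps(_rounded(rep.to_json()), indent=2))
            manifest.add_output(path)
        manifest.write(out / "manifest.json")
    return result


def _rounded(obj, ndigits: int = 12):
    """Round floats recursively so report digests are platform-stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _rounded(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_rounded(v, ndigits) for v in obj]
    return obj


def _tune_ridge(
    models: TrainedModels,
    train: Sequence[ObservationWindow],
    tune: Sequence[ObservationWindow],
    config: PipelineConfig,
) -> TrainedModels:
    """Pick the ridge strength maximising the tuning-split criterion."""
    if config.tuning_criterion != "auroc":
        raise ValueError("only the AUROC tuning criterion is implemented")
    y = _labels(train)
    emb = _embedding_features(models.embedding, train, config.embedding_weighting)
    emb_cols = tuple(f"e{i}" for i in range(emb.shape[1]))
    best = models
    best_score = -np.inf
    for lam in config.tune_ridge_grid:
        to_model = fit_logistic(FeatureBlock(emb, emb_cols), y, penalty=lam,
                                variant="TO")
        tc_matrix = np.column_stack(
            [emb, _coded_features(train, models.selected_codes)]
        )
        tc_cols = emb_cols + ("age", "sex_female") + tuple(models.selected_codes)
        tc_model = fit_logistic(FeatureBlock(tc_matrix, tc_cols), y, penalty=lam,
                                variant="TC")
        trial = TrainedModels(models.embedding, models.selected_codes,
                              to_model, tc_model)
        score = auroc(predict_windows(trial, tune, config)["TO"])
        if score > best_score:
            best, best_score = trial, score
    return best


@dataclass
class ExternalResult:
    per_centre: dict[str, dict[str, MetricReport]]  # centre -> model -> report
    overall: dict[str, MetricReport]
    stacked: dict[str, PredictionSet]
    excluded_centres: list[str]
    manifest: RunManifest


def leave_centre_out(
    windows: Sequence[ObservationWindow],
    config: PipelineConfig,
) -> ExternalResult:
    """Leave-one-centre-out external validation with stacked predictions."""
    manifest = _manifest_start(config)
    centres = sorted({w.centre_id for w in windows})
    if len(centres) < 2:
        raise ValueError("leave-centre-out requires at least 2 centres")

    per_centre: dict[str, dict[str, MetricReport]] = {}
    stacks: dict[str, list[PredictionSet]] = {"TO": [], "TC": []}
    excluded: list[str] = []
    for centre in centres:
        held = [w for w in windows if w.centre_id == centre]
        rest = [w for w in windows if w.centre_id != centre]
        held_y = _labels(held)
        if held_y.min() == held_y.max():
            warnings.warn(
                f"centre {centre} has a single outcome class; fold skipped"
            )
            excluded.append(centre)
            continue
        train_ids = {w.patient_id for w in rest}
        assert not train_ids & {w.patient_id for w in held}
        models = fit_pipeline(rest, config)
        preds = predict_windows(models, held, config)
        per_centre[centre] = {
            name: build_metric_report(
                ps,
                name=f"external-{name}-{centre}",
                B=config.bootstrap_B,
                seed=config.seed,
                ppv_targets=config.ppv_targets,
                with_operating_cis=config.with_operating_cis,
            )
            for name, ps in preds.items()
        }
        for name, ps in preds.items():
            stacks[name].append(ps)
        _log(
            f"[external] centre {centre}: TO AUROC="
            f"{per_centre[centre]['TO'].auroc[0]:.4f} (n={len(held)})"
        )

    stacked = {name: concatenate(sets) for name, sets in stacks.items()}
    overall = {
        name: build_metric_report(
            ps,
            name=f"external-{name}-overall",
            B=config.bootstrap_B,
            seed=config.seed,
            ppv_targets=config.ppv_targets,
            with_operating_cis=config.with_operating_cis,
        )
        for name, ps in stacked.items()
    }
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.stage_counts["stacked_n"] = stacked["TO"].n
    return ExternalResult(per_centre, overall, stacked, excluded, manifest)


def run_external(
    records,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> tuple[ExternalResult, list[dict]]:
    """External validation over a cohort of records; returns the result
    plus rows shaped like a per-centre + overall evaluation table."""
    windows, _ = build_cohort_windows(
        records,
        lead_months=config.lead_months,
        span_months=config.span_months,
        min_age=config.min_age,
        min_history_months=config.min_history_months,
        require_text=config.require_text,
    )
    result = leave_centre_out(windows, config)
    rows: list[dict] = []
    for model_name in ("TO", "TC"):
        for centre in sorted(result.per_centre):
            rep = result.per_centre[centre][model_name]
            rows.append(_table_row(model_name, centre, rep))
        rows.append(_table_row(model_name, "Overall", result.overall[model_name]))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "external_validation.tsv"
        _write_table(rows, path)
        result.manifest.add_output(path)
        result.manifest.write(out / "manifest.json")
    return result, rows


def _table_row(model: str, test_set: str, rep: MetricReport) -> dict:
    return {
        "model": model,
        "test_set": test_set,
        "auroc": rep.auroc[0],
        "auroc_ci_lower": rep.auroc[1],
        "auroc_ci_upper": rep.auroc[2],
        "auprc": rep.auprc[0],
        "auprc_ci_lower": rep.auprc[1],
        "auprc_ci_upper": rep.auprc[2],
        "brier": rep.brier[0],
        "brier_ci_lower": rep.brier[1],
        "brier_ci_upper": rep.brier[2],
        "n": rep.n,
    }


def _write_table(rows: list[dict], path: str | Path) -> None:
    if not rows:
        Path(path).write_text("")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append(
            "\t".join(
                f"{row[c]:.6f}" if isinstance(row[c], float) else str(row[c])
                for c in cols
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_leadtime_sweep(
    records,
    config: PipelineConfig,
    leads: Sequence[int] = (2, 3, 4, 5, 6),
    out_dir: str | Path | None = None,
) -> list[dict]:
    """Internal validation per lead time (shared seed); one row per lead."""
    rows: list[dict] = []
    for lead in leads:
        cfg = dataclasses.replace(config, lead_months=lead)
        try:
            res = run_internal(records, cfg)
        except ValueError as exc:
            warnings.warn(f"lead {lead}: {exc}")
            rows.append({"lead_months": lead, "status": "absent",
                         "auroc_TO": float("nan"), "auprc_TO": float("nan"),
                         "auroc_TC": float("nan"), "auprc_TC": float("nan")})
            continue
        rows.append(
            {
                "lead_months": lead,
                "status": "ok",
                "auroc_TO": res.reports["TO"].auroc[0],
                "auprc_TO": res.reports["TO"].auprc[0],
                "auroc_TC": res.reports["TC"].auroc[0],
                "auprc_TC": res.reports["TC"].auprc[0],
            }
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_table(rows, out / "leadtime_sweep.tsv")
    return rows
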