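"""Logistic risk models: text-only (TO) and text-plus-codes (TC).

TO regresses the outcome on the document embedding alone; TC adds age,
a sex indicator (female = 1), and the per-window counts of the selected
ICPC codes.  Fitting is maximum (optionally ridge-penalised) Bernoulli
likelihood via iteratively reweighted least squares; predictors are
standardised with parameters frozen on the training rows.  The ICPC
predictor set itself is chosen by backward stepwise elimination on the
Akaike information criterion over a coded-features-only model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class SeparationError(RuntimeError):
    """Unpenalised likelihood has no maximiser (complete separation)."""


class SchemaError(ValueError):
    """Feature columns do not match the fitted model."""


@dataclass
class Scaler:
    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.means) / self.sds

    def param_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update("|".join(self.columns).encode())
        h.update(np.ascontiguousarray(self.means).tobytes())
        h.update(np.ascontiguousarray(self.sds).tobytes())
        return h.hexdigest()


@dataclass
class FeatureBlock:
    """A design matrix with named columns and (optionally) a fitted scaler."""

    matrix: np.ndarray
    columns: tuple[str, ...]
    scaler: Scaler | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(self.columns)]
        for row in self.matrix:
            lines.append("\t".join(f"{v:.10g}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureBlock":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        columns = tuple(lines[0].split("\t"))
        matrix = np.array(
            [[float(v) for v in line.split("\t")] for line in lines[1:]]
        ).reshape(-1, len(columns))
        return cls(matrix, columns)

    def fit_scaler(self) -> Scaler:
        """Fit per-column standardisation on these (training) rows."""
        means = self.matrix.mean(axis=0) if self.n else np.zeros(len(self.columns))
        sds = self.matrix.std(axis=0) if self.n else np.ones(len(self.columns))
        sds = np.where(sds < 1e-12, 1.0, sds)
        self.scaler = Scaler(tuple(self.columns), means, sds)
        return self.scaler


@dataclass
class RiskModel:
    variant: str  # "TO" | "TC" | free-form
    columns: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray  # aligned to columns, on the standardised scale
    scaler: Scaler
    log_likelihood: float
    converged: bool
    n_iter: int
    penalty: float = 0.0

    def to_json(self, path: str | Path) -> None:
        obj = {
            "variant": self.variant,
            "columns": list(self.columns),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "scaler_means": self.scaler.means.tolist(),
            "scaler_sds": self.scaler.sds.tolist(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "penalty": self.penalty,
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # ll = sum y*eta - log(1 + exp(eta)), stable
    return float((y * eta).sum() - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    features: FeatureBlock,
    labels: Sequence[int],
    penalty: float = 0.0,
    variant: str = "custom",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> RiskModel:
    """Fit a (ridge-penalised) logistic regression by IRLS.

    ``penalty`` is the ridge strength lambda on the standardised
    coefficients (the intercept is never penalised); ``penalty=0`` is
    plain maximum likelihood, which raises :class:`SeparationError`
    when the data are separable.  Convergence: relative change of the
    penalised log-likelihood below ``tol``, or ``max_iter`` sweeps.
    """
    y = np.asarray(labels, dtype=float)
    if y.shape[0] != features.n:
        raise ValueError("labels length does not match feature rows")
    if y.min() == y.max():
        raise ValueError("degenerate labels: need both classes")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")

    scaler = features.scaler or features.fit_scaler()
    Xs = scaler.transform(features.matrix)
    n, p = Xs.shape
    X = np.column_stack([np.ones(n), Xs])
    pen = np.zeros(p + 1)
    pen[1:] = penalty

    beta = np.zeros(p + 1)
    pbar = y.mean()
    beta[0] = np.log(pbar / (1.0 - pbar))
    eta = X @ beta
    ll = _bernoulli_loglik(y, eta) - 0.5 * float(pen @ (beta ** 2))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu) - pen * beta
        H = (X.T * w) @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H = H + np.eye(p + 1) * 1e-8
            step = np.linalg.solve(H, grad)

        # damped Newton: halve the step until the objective improves
        new_beta = beta + step
        new_eta = X @ new_beta
        new_ll = _bernoulli_loglik(y, new_eta) - 0.5 * float(
            pen @ (new_beta ** 2)
        )
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_eta = X @ new_beta
            new_ll = _bernoulli_loglik(y, new_eta) - 0.5 * float(
                pen @ (new_beta ** 2)
            )
            halvings += 1
        beta, eta = new_beta, new_eta
        if penalty == 0.0 and np.abs(beta[1:]).max(initial=0.0) > 40.0:
            raise SeparationError(
                "complete or quasi-complete separation detected; refit with "
                "a ridge penalty (penalty > 0)"
            )
        if abs(new_ll - ll) <= tol * (abs(ll) + 1e-12):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    # a (near-)perfect unpenalised fit means the likelihood has no
    # finite maximiser: the data are separated
    if penalty == 0.0 and _bernoulli_loglik(y, eta) > -1e-6:
        raise SeparationError(
            "complete or quasi-complete separation detected; refit with "
            "a ridge penalty (penalty > 0)"
        )
    return RiskModel(
        variant=variant,
        columns=tuple(features.columns),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        scaler=scaler,
        log_likelihood=_bernoulli_loglik(y, eta),
        converged=converged,
        n_iter=it,
        penalty=penalty,
    )


def predict_risk(model: RiskModel, features: FeatureBlock) -> np.ndarray:
    """Predicted probabilities; columns must align with the fitted model."""
    if tuple(features.columns) != model.columns:
        missing = set(model.columns) - set(features.columns)
        extra = set(features.columns) - set(model.columns)
        raise SchemaError(
            f"feature columns do not match model: missing={sorted(missing)}, "
            f"extra={sorted(extra)}"
        )
    Xs = model.scaler.transform(features.matrix)
    eta = model.intercept + Xs @ model.coefficients
    return _sigmoid(eta)


def model_aic(model: RiskModel) -> float:
    """AIC = 2k - 2 lnL with k = intercept + coefficient count."""
    k = 1 + len(model.columns)
    return 2.0 * k - 2.0 * model.log_likelihood


def _fit_subset(
    base: FeatureBlock | None,
    candidate_matrix: np.ndarray,
    candidate_names: Sequence[str],
    subset: Sequence[str],
    labels: Sequence[int],
) -> RiskModel:
    name_to_col = {c: i for i, c in enumerate(candidate_names)}
    cols = [name_to_col[c] for c in subset]
    parts = []
    names: list[str] = []
    if base is not None:
        parts.append(base.matrix)
        names.extend(base.columns)
    if cols:
        parts.append(candidate_matrix[:, cols])
        names.extend(subset)
    if not parts:
        parts.append(np.empty((len(np.asarray(labels)), 0)))
    block = FeatureBlock(np.column_stack(parts) if parts else parts[0],
                         tuple(names))
    model = fit_logistic(block, labels, penalty=0.0, variant="aic-step")
    if not np.isfinite(model.log_likelihood):
        raise RuntimeError(
            f"non-finite likelihood during AIC step with subset {subset}"
        )
    return model


def backward_aic(
    candidate_names: Sequence[str],
    candidate_matrix: np.ndarray,
    labels: Sequence[int],
    base: FeatureBlock | None = None,
) -> list[str]:
    """Backward stepwise elimination of candidate columns by AIC.

    Starts from the full candidate set and repeatedly drops the single
    column whose removal most decreases the AIC, stopping when no
    removal improves it.  Ties are broken by removing the
    alphabetically-last candidate.  ``base`` columns (e.g. age and sex)
    are always kept.
    """
    selected = sorted(candidate_names)
    if not selected:
        return []
    candidate_matrix = np.asarray(candidate_matrix, dtype=float)
    current_aic = model_aic(
        _fit_subset(base, candidate_matrix, candidate_names, selected, labels)
    )
    while selected:
        best_aic = current_aic
        best_drop: str | None = None
        # alphabetical scan; ">=" keeps the alphabetically-last tied drop
        for drop in selected:
            trial = [c for c in selected if c != drop]
            aic = model_aic(
                _fit_subset(base, candidate_matrix, candidate_names, trial, labels)
            )
            if aic < best_aic or (best_drop is not None and aic == best_aic):
                best_aic = aic
                best_drop = drop
        if best_drop is None:
            break
        selected = [c for c in selected if c != best_drop]
        current_aic = best_aic
    return selected
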