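"""Neural-network surrogate of structural -> release parameters.

A single-hidden-layer perceptron (4 inputs, 2-7 hidden units, 4 outputs;
tangent-sigmoid hidden activation, logistic-sigmoid output activation)
approximates the map from formulation structure (feeding ratio, CS%,
Fe3O4%, 5FU%) to release parameters (BR, TRmax, RTRmax, Le). Inputs are
normalized to the bipolar interval [-1, 1]; outputs to [0.1, 0.9] so the
targets sit inside the logistic range.

Training minimizes the Bayesian-regularized objective

    F(w) = beta * E_D + alpha * E_W,
    E_D = sum of squared residuals,  E_W = sum of squared weights,

by Levenberg-Marquardt steps, with alpha and beta re-estimated after every
accepted step from the Gauss-Newton evidence approximation
(gamma = N_w - 2*alpha*tr(H^-1), alpha = gamma/(2 E_W),
beta = (n - gamma)/(2 E_D)). The effective number of parameters gamma is
reported with each fit. Regularization can be switched off (alpha pinned
at 0) to obtain the plain least-squares network for comparison.

Because only 54 real records exist (18 runs x 3 replicates), two
small-data strategies are provided and compared: k-fold cross validation
and Gaussian-noise augmentation (zero-mean noise, default SD 0.05 on the
normalized scale, 10 noisy copies per record). The default training
protocol mirrors the study: augment all 54 records, train on the 540
derived plus 18 real records (replicate 1 of each run), test on the
remaining 36 real records. That protocol leaks test information through
the augmented copies and the normalization; ``leakage=False`` restricts
augmentation and normalization to the 18 training records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .datamodel import ExperimentRecord, FormulationParams, ReleaseParams
from .exceptions import (
    DegenerateVariableWarning,
    DomainError,
    ExtrapolationWarning,
    FitError,
)

INPUT_FIELDS = ("feeding_ratio", "cs_percent", "np_percent", "drug_percent")
OUTPUT_FIELDS = ("br", "trmax", "rtrmax", "le")

MIN_TRAINING_RECORDS = 20


def records_to_xy(records: Iterable[ExperimentRecord]):
    """Stack records into raw (X, Y) arrays, columns per INPUT/OUTPUT_FIELDS."""
    X, Y = [], []
    for rec in records:
        f, y = rec.formulation, rec.response
        X.append([getattr(f, k) for k in INPUT_FIELDS])
        Y.append([getattr(y, k) for k in OUTPUT_FIELDS])
    return np.asarray(X, dtype=float), np.asarray(Y, dtype=float)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationSpec:
    """Per-variable min/max linear map onto a target interval."""

    lo: np.ndarray
    hi: np.ndarray
    interval: tuple = (-1.0, 1.0)

    def __post_init__(self):
        object.__setattr__(self, "lo", np.atleast_1d(np.asarray(self.lo, dtype=float)))
        object.__setattr__(self, "hi", np.atleast_1d(np.asarray(self.hi, dtype=float)))

    @property
    def _degenerate(self) -> np.ndarray:
        return self.hi <= self.lo

    def apply(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        a, b = self.interval
        span = np.where(self._degenerate, 1.0, self.hi - self.lo)
        Z = a + (X - self.lo) * (b - a) / span
        return np.where(self._degenerate, 0.5 * (a + b), Z)

    def invert(self, Z) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        a, b = self.interval
        span = np.where(self._degenerate, 1.0, self.hi - self.lo)
        X = self.lo + (Z - a) * span / (b - a)
        return np.where(self._degenerate, self.lo, X)


def fit_normalization(values, interval=(-1.0, 1.0)) -> NormalizationSpec:
    """Fit observed per-column min/max; constant columns map to the midpoint."""
    V = np.atleast_2d(np.asarray(values, dtype=float))
    lo, hi = V.min(axis=0), V.max(axis=0)
    if np.any(hi <= lo):
        cols = np.nonzero(hi <= lo)[0].tolist()
        warnings.warn(f"constant column(s) {cols} map to the interval midpoint",
                      DegenerateVariableWarning)
    return NormalizationSpec(lo=lo, hi=hi, interval=tuple(interval))


# ---------------------------------------------------------------------------
# Augmentation and folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationConfig:
    """Gaussian-noise augmentation on the normalized scale."""

    mean: float = 0.0
    sd: float = 0.05
    replicates_per_record: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.sd <= 0.5):
            raise DomainError(
                f"augmentation sd={self.sd} nonsensical on the normalized scale")
        if self.replicates_per_record < 1:
            raise DomainError("replicates_per_record must be >= 1")


def augment_gaussian(Xn: np.ndarray, Yn: np.ndarray,
                     config: AugmentationConfig):
    """Noisy copies of normalized records; originals are not included.

    Each record yields ``replicates_per_record`` copies with independent
    Gaussian noise added to inputs and outputs alike.
    """
    rng = np.random.default_rng(config.seed)
    R = config.replicates_per_record
    Xa = np.repeat(Xn, R, axis=0)
    Ya = np.repeat(Yn, R, axis=0)
    if config.sd > 0 or config.mean != 0:
        Xa = Xa + rng.normal(config.mean, config.sd, size=Xa.shape)
        Ya = Ya + rng.normal(config.mean, config.sd, size=Ya.shape)
    return Xa, Ya


def kfold_split(n_records: int, k: int = 10, seed: int = 0) -> list:
    """Disjoint shuffled folds covering range(n_records); sizes differ by <= 1."""
    if k > n_records:
        raise DomainError(f"k={k} exceeds n_records={n_records}")
    if k < 2:
        raise DomainError("k must be >= 2")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n_records))]


# ---------------------------------------------------------------------------
# Network internals
# ---------------------------------------------------------------------------

def _n_weights(n_in: int, h: int, n_out: int) -> int:
    return h * n_in + h + n_out * h + n_out


def _unpack(w: np.ndarray, n_in: int, h: int, n_out: int):
    i = 0
    W1 = w[i:i + h * n_in].reshape(h, n_in); i += h * n_in
    b1 = w[i:i + h]; i += h
    W2 = w[i:i + n_out * h].reshape(n_out, h); i += n_out * h
    b2 = w[i:i + n_out]
    return W1, b1, W2, b2


def _forward(w, X, n_in, h, n_out):
    W1, b1, W2, b2 = _unpack(w, n_in, h, n_out)
    A1 = np.tanh(X @ W1.T + b1)
    Z2 = A1 @ W2.T + b2
    Y = 1.0 / (1.0 + np.exp(-Z2))
    return Y, A1


def _jacobian(w, X, n_in, h, n_out):
    """Jacobian of the flattened outputs w.r.t. the weight vector."""
    n = X.shape[0]
    W1, b1, W2, b2 = _unpack(w, n_in, h, n_out)
    A1 = np.tanh(X @ W1.T + b1)                      # (n, h)
    Y = 1.0 / (1.0 + np.exp(-(A1 @ W2.T + b2)))      # (n, o)
    S = Y * (1.0 - Y)                                # dY/dZ2
    D1 = 1.0 - A1 ** 2                               # (n, h)
    eye = np.eye(n_out)

    G = S[:, :, None] * W2[None, :, :] * D1[:, None, :]          # (n, o, h)
    J_W1 = (G[:, :, :, None] * X[:, None, None, :]).reshape(n, n_out, h * n_in)
    J_b1 = G
    J_W2 = np.einsum("no,op,nh->noph", S, eye, A1).reshape(n, n_out, n_out * h)
    J_b2 = np.einsum("no,op->nop", S, eye)
    J = np.concatenate([J_W1, J_b1, J_W2, J_b2], axis=2)
    return J.reshape(n * n_out, -1), Y


def _train_network(Xn, Yn, hidden, seed, max_iter=150, bayes=True,
                   tol=1e-10):
    """Levenberg-Marquardt training of the regularized objective.

    Returns (weights, info) with the training summary: final objective,
    alpha/beta, effective parameter count gamma, iterations, convergence.
    """
    n_in, n_out = Xn.shape[1], Yn.shape[1]
    nw = _n_weights(n_in, hidden, n_out)
    n_res = Xn.shape[0] * n_out
    rng = np.random.default_rng(seed)
    w = rng.uniform(-0.5, 0.5, nw)

    alpha = 1e-4 if bayes else 0.0
    beta = 1.0
    mu = 1e-3
    eye = np.eye(nw)

    Yhat, _ = _forward(w, Xn, n_in, hidden, n_out)
    r = (Yhat - Yn).ravel()
    ED, EW = float(r @ r), float(w @ w)
    gamma = float(nw)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J, _ = _jacobian(w, Xn, n_in, hidden, n_out)
        JtJ = J.T @ J
        g = 2.0 * (beta * (J.T @ r) + alpha * w)
        F = beta * ED + alpha * EW
        if not np.isfinite(F):
            raise FitError("training objective became non-finite")

        accepted = False
        delta = np.zeros(nw)
        for _ in range(30):
            A = 2.0 * beta * JtJ + (2.0 * alpha + mu) * eye
            try:
                delta = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_new = w + delta
            Yhat, _ = _forward(w_new, Xn, n_in, hidden, n_out)
            r_new = (Yhat - Yn).ravel()
            ED_new, EW_new = float(r_new @ r_new), float(w_new @ w_new)
            if beta * ED_new + alpha * EW_new < F:
                accepted = True
                mu = max(mu / 10.0, 1e-12)
                break
            mu *= 10.0
            if mu > 1e10:
                break
        if not accepted:
            converged = True  # no descent direction left at this scale
            break
        w, r, ED, EW = w_new, r_new, ED_new, EW_new

        if bayes:
            J, _ = _jacobian(w, Xn, n_in, hidden, n_out)
            H = 2.0 * beta * (J.T @ J) + 2.0 * alpha * eye
            try:
                tr_inv = float(np.trace(np.linalg.inv(H)))
            except np.linalg.LinAlgError:
                tr_inv = float(np.trace(np.linalg.pinv(H)))
            gamma = float(np.clip(nw - 2.0 * alpha * tr_inv, 1e-6, nw))
            alpha = gamma / (2.0 * EW) if EW > 1e-12 else 1e6
            if ED > 1e-12 and n_res > gamma:
                beta = (n_res - gamma) / (2.0 * ED)

        if np.max(np.abs(delta)) < tol * (1.0 + np.max(np.abs(w))):
            converged = True
            break

    if not converged:
        warnings.warn(f"network training stopped at max_iter={max_iter} "
                      "without meeting the step tolerance")
    info = {
        "objective": beta * ED + alpha * EW,
        "sse": ED, "weight_ss": EW,
        "alpha": alpha, "beta": beta, "gamma": gamma,
        "n_weights": nw, "iterations": it, "converged": converged,
        "bayes": bayes, "seed": int(seed),
    }
    return w, info


# ---------------------------------------------------------------------------
# Model surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateConfig:
    """Architecture and training settings of the 4-H-4 surrogate."""

    hidden_units: int = 6
    repeats: int = 10
    max_iter: int = 150
    seed: int = 0
    input_interval: tuple = (-1.0, 1.0)
    output_interval: tuple = (0.1, 0.9)
    bayes: bool = True

    def __post_init__(self):
        if not (2 <= self.hidden_units <= 7):
            raise DomainError(f"hidden_units={self.hidden_units} outside [2, 7]")
        if self.repeats < 1:
            raise DomainError("repeats must be >= 1")


@dataclass(frozen=True)
class FitMetrics:
    """Mean squared error (normalized scale) and pooled R^2."""

    mse: float
    r2: float

    def __post_init__(self):
        if self.mse < 0:
            raise DomainError("mse must be >= 0")


def evaluate_metrics(predictions, truths) -> FitMetrics:
    """MSE and R^2 pooled over output columns (column-wise means for SS_tot)."""
    P = np.asarray(predictions, dtype=float)
    T = np.asarray(truths, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if T.ndim == 1:
        T = T[:, None]
    if P.shape != T.shape or P.shape[0] < 2:
        raise DomainError(f"need equal shapes with >= 2 rows, got {P.shape} vs {T.shape}")
    ss_tot = float(np.sum((T - T.mean(axis=0)) ** 2))
    if ss_tot == 0.0:
        raise DomainError("truths have zero variance; R^2 undefined")
    ss_res = float(np.sum((P - T) ** 2))
    return FitMetrics(mse=ss_res / P.size, r2=1.0 - ss_res / ss_tot)


@dataclass
class SurrogateModel:
    """A trained 4-H-4 network with its normalization and training summary."""

    weights: np.ndarray
    hidden_units: int
    input_norm: NormalizationSpec
    output_norm: NormalizationSpec
    training: dict
    config: SurrogateConfig

    @property
    def gamma(self) -> float:
        """Effective number of parameters from the evidence framework."""
        return self.training["gamma"]

    def predict_array(self, X) -> np.ndarray:
        """Vectorized raw-scale predictions, clipped to physical ranges.

        No extrapolation warning is raised here (the GA legitimately probes
        the whole chromosome box); use ``predict`` for single formulations
        with hull checking.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Zin = self.input_norm.apply(X)
        Yn, _ = _forward(self.weights, Zin, len(INPUT_FIELDS),
                         self.hidden_units, len(OUTPUT_FIELDS))
        Y = self.output_norm.invert(Yn)
        br, trmax, rtrmax, le = (Y[:, i] for i in range(4))
        rtrmax = np.clip(rtrmax, 0.0, 100.0)
        br = np.clip(br, 0.0, rtrmax)
        trmax = np.maximum(trmax, 1e-6)
        le = np.clip(le, 1e-6, 100.0)
        return np.column_stack([br, trmax, rtrmax, le])

    def predict(self, formulation: FormulationParams) -> ReleaseParams:
        """Predict release parameters for one formulation."""
        x = np.array([[getattr(formulation, k) for k in INPUT_FIELDS]])
        if np.any(x < self.input_norm.lo) or np.any(x > self.input_norm.hi):
            warnings.warn(
                "formulation lies outside the training hull; prediction is an "
                "extrapolation", ExtrapolationWarning)
        br, trmax, rtrmax, le = self.predict_array(x)[0]
        return ReleaseParams(br=float(br), trmax=float(trmax),
                             rtrmax=float(rtrmax), le=float(le))

    def summary(self) -> str:
        t = self.training
        lines = [
            f"Release surrogate: {len(INPUT_FIELDS)}-{self.hidden_units}-"
            f"{len(OUTPUT_FIELDS)} perceptron (tanh / logistic)",
            f"  training: {'Bayesian-regularized' if t['bayes'] else 'unregularized'}"
            f" Levenberg-Marquardt, {t['iterations']} iterations"
            f" ({'converged' if t['converged'] else 'iteration cap'})",
            f"  objective F = beta*E_D + alpha*E_W = {t['objective']:.6g}"
            f"  (alpha={t['alpha']:.4g}, beta={t['beta']:.4g})",
            f"  effective parameters gamma = {t['gamma']:.2f} of {t['n_weights']}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "hidden_units": self.hidden_units,
            "input_norm": {"lo": self.input_norm.lo.tolist(),
                           "hi": self.input_norm.hi.tolist(),
                           "interval": list(self.input_norm.interval)},
            "output_norm": {"lo": self.output_norm.lo.tolist(),
                            "hi": self.output_norm.hi.tolist(),
                            "interval": list(self.output_norm.interval)},
            "training": self.training,
            "config": self.config.__dict__ | {
                "input_interval": list(self.config.input_interval),
                "output_interval": list(self.config.output_interval)},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateModel":
        d = json.loads(Path(path).read_text())
        cfg = d["config"]
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            hidden_units=int(d["hidden_units"]),
            input_norm=NormalizationSpec(
                lo=np.asarray(d["input_norm"]["lo"]), hi=np.asarray(d["input_norm"]["hi"]),
                interval=tuple(d["input_norm"]["interval"])),
            output_norm=NormalizationSpec(
                lo=np.asarray(d["output_norm"]["lo"]), hi=np.asarray(d["output_norm"]["hi"]),
                interval=tuple(d["output_norm"]["interval"])),
            training=d["training"],
            config=SurrogateConfig(**{**cfg, "input_interval": tuple(cfg["input_interval"]),
                                      "output_interval": tuple(cfg["output_interval"])}),
        )


class ReleaseSurrogate:
    """Model object built from raw (X, Y); ``fit()`` returns a SurrogateModel.

    ``X`` columns follow INPUT_FIELDS and ``Y`` columns OUTPUT_FIELDS, both
    on the raw (unnormalized) scale. Extra pre-normalized training rows
    (e.g. augmented records) can be supplied via ``extra_normalized``.
    """

    def __init__(self, X, Y, config: Optional[SurrogateConfig] = None,
                 input_norm: Optional[NormalizationSpec] = None,
                 output_norm: Optional[NormalizationSpec] = None,
                 extra_normalized: Optional[tuple] = None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise DomainError("X and Y must have the same number of rows")
        self.config = config if config is not None else SurrogateConfig()
        self.input_norm = input_norm if input_norm is not None else fit_normalization(
            self.X, self.config.input_interval)
        self.output_norm = output_norm if output_norm is not None else fit_normalization(
            self.Y, self.config.output_interval)
        self.extra_normalized = extra_normalized

    @classmethod
    def from_records(cls, records: Sequence[ExperimentRecord],
                     config: Optional[SurrogateConfig] = None, **kw) -> "ReleaseSurrogate":
        X, Y = records_to_xy(records)
        return cls(X, Y, config=config, **kw)

    def fit(self, seed: Optional[int] = None) -> SurrogateModel:
        Xn = self.input_norm.apply(self.X)
        Yn = self.output_norm.apply(self.Y)
        if self.extra_normalized is not None:
            Xe, Ye = self.extra_normalized
            Xn = np.vstack([np.atleast_2d(Xe), Xn])
            Yn = np.vstack([np.atleast_2d(Ye), Yn])
        if Xn.shape[0] < MIN_TRAINING_RECORDS:
            raise DomainError(
                f"need >= {MIN_TRAINING_RECORDS} training records, have {Xn.shape[0]}")
        cfg = self.config
        w, info = _train_network(Xn, Yn, cfg.hidden_units,
                                 seed=cfg.seed if seed is None else seed,
                                 max_iter=cfg.max_iter, bayes=cfg.bayes)
        return SurrogateModel(weights=w, hidden_units=cfg.hidden_units,
                              input_norm=self.input_norm, output_norm=self.output_norm,
                              training=info, config=cfg)


def train_surrogate(records_or_xy, config: Optional[SurrogateConfig] = None,
                    seed: Optional[int] = None, **kw) -> SurrogateModel:
    """Train a surrogate from records or a raw (X, Y) pair."""
    if isinstance(records_or_xy, tuple):
        model = ReleaseSurrogate(*records_or_xy, config=config, **kw)
    else:
        model = ReleaseSurrogate.from_records(records_or_xy, config=config, **kw)
    return model.fit(seed=seed)


# ---------------------------------------------------------------------------
# Study protocol: data preparation, node sweep, strategy comparison
# ---------------------------------------------------------------------------

@dataclass
class SurrogateData:
    """Normalized train/test arrays under the study's split protocol."""

    X_train: np.ndarray
    Y_train: np.ndarray
    X_test: np.ndarray
    Y_test: np.ndarray
    input_norm: NormalizationSpec
    output_norm: NormalizationSpec
    n_real_train: int
    n_augmented: int


def prepare_surrogate_data(records: Sequence[ExperimentRecord],
                           augmentation: Optional[AugmentationConfig] = None,
                           config: Optional[SurrogateConfig] = None,
                           leakage: bool = True,
                           train_replicate: int = 1) -> SurrogateData:
    """Split records by replicate and optionally augment the training side.

    Replicate ``train_replicate`` of every run forms the real training set
    (18 records); the other replicates form the test set (36 records). With
    ``leakage=True`` (the study's literal protocol) all records are both
    normalized over and augmented; with ``leakage=False`` only the training
    records inform normalization and augmentation.
    """
    cfg = config if config is not None else SurrogateConfig()
    train_recs = [r for r in records if r.replicate == train_replicate]
    test_recs = [r for r in records if r.replicate != train_replicate]
    if not train_recs or not test_recs:
        raise DomainError("records must contain both the training replicate and others")
    Xtr, Ytr = records_to_xy(train_recs)
    Xte, Yte = records_to_xy(test_recs)

    norm_X, norm_Y = (np.vstack([Xtr, Xte]), np.vstack([Ytr, Yte])) if leakage \
        else (Xtr, Ytr)
    input_norm = fit_normalization(norm_X, cfg.input_interval)
    output_norm = fit_normalization(norm_Y, cfg.output_interval)

    Xtr_n, Ytr_n = input_norm.apply(Xtr), output_norm.apply(Ytr)
    Xte_n, Yte_n = input_norm.apply(Xte), output_norm.apply(Yte)

    n_aug = 0
    X_parts, Y_parts = [Xtr_n], [Ytr_n]
    if augmentation is not None:
        src_X = np.vstack([Xtr_n, Xte_n]) if leakage else Xtr_n
        src_Y = np.vstack([Ytr_n, Yte_n]) if leakage else Ytr_n
        Xa, Ya = augment_gaussian(src_X, src_Y, augmentation)
        n_aug = Xa.shape[0]
        X_parts.insert(0, Xa)
        Y_parts.insert(0, Ya)
    return SurrogateData(
        X_train=np.vstack(X_parts), Y_train=np.vstack(Y_parts),
        X_test=Xte_n, Y_test=Yte_n,
        input_norm=input_norm, output_norm=output_norm,
        n_real_train=len(train_recs), n_augmented=n_aug)


def _train_on_normalized(data_X, data_Y, cfg: SurrogateConfig, seed: int):
    if data_X.shape[0] < MIN_TRAINING_RECORDS:
        raise DomainError(
            f"need >= {MIN_TRAINING_RECORDS} training records, have {data_X.shape[0]}")
    return _train_network(data_X, data_Y, cfg.hidden_units, seed=seed,
                          max_iter=cfg.max_iter, bayes=cfg.bayes)


def _repeat_metrics(data: SurrogateData, cfg: SurrogateConfig):
    """Train ``cfg.repeats`` seeded networks; mean train/test metrics."""
    n_in, n_out = data.X_train.shape[1], data.Y_train.shape[1]
    tr_mse, tr_r2, te_mse, te_r2 = [], [], [], []
    best = None
    for rep in range(cfg.repeats):
        seed = cfg.seed * 100003 + cfg.hidden_units * 1009 + rep
        w, info = _train_on_normalized(data.X_train, data.Y_train, cfg, seed)
        Ptr, _ = _forward(w, data.X_train, n_in, cfg.hidden_units, n_out)
        Pte, _ = _forward(w, data.X_test, n_in, cfg.hidden_units, n_out)
        mtr = evaluate_metrics(Ptr, data.Y_train)
        mte = evaluate_metrics(Pte, data.Y_test)
        tr_mse.append(mtr.mse); tr_r2.append(mtr.r2)
        te_mse.append(mte.mse); te_r2.append(mte.r2)
        if best is None or mte.mse < best[0]:
            best = (mte.mse, w, info)
    means = {"train_mse": float(np.mean(tr_mse)), "train_r2": float(np.mean(tr_r2)),
             "test_mse": float(np.mean(te_mse)), "test_r2": float(np.mean(te_r2))}
    return means, best


def select_hidden_units(data: SurrogateData,
                        candidates: Sequence[int] = tuple(range(2, 8)),
                        config: Optional[SurrogateConfig] = None):
    """Sweep hidden-unit counts; pick the argmin of mean test MSE.

    Each candidate is trained ``repeats`` times from different seeds and
    the metrics averaged, as in the study's node search. Returns
    ``(best_count, table)`` with one row per candidate.
    """
    cfg = config if config is not None else SurrogateConfig()
    rows = []
    failures = {}
    for h in candidates:
        hcfg = replace(cfg, hidden_units=int(h))
        try:
            means, _ = _repeat_metrics(data, hcfg)
        except (FitError, DomainError) as exc:
            failures[h] = str(exc)
            continue
        rows.append({"hidden_units": int(h), **means})
    if not rows:
        raise FitError(f"all hidden-unit candidates failed: {failures}")
    table = pd.DataFrame(rows)
    best = int(table.loc[table["test_mse"].idxmin(), "hidden_units"])
    return best, table


@dataclass(frozen=True)
class StrategyComparison:
    """Test metrics of the two small-data strategies and the winner."""

    gaussian: FitMetrics
    cross_validation: FitMetrics
    winner: str


def compare_augmentation_vs_cv(records: Sequence[ExperimentRecord],
                               augmentation: Optional[AugmentationConfig] = None,
                               k: int = 10,
                               config: Optional[SurrogateConfig] = None,
                               leakage: bool = True) -> StrategyComparison:
    """Gaussian-noise augmentation vs k-fold CV on the same records.

    The augmentation arm follows the split protocol of
    ``prepare_surrogate_data`` and reports test metrics averaged over
    ``repeats`` seeded trainings. The CV arm trains on k-1 folds of the
    raw records and averages held-out metrics over folds. The winner is
    the strategy with lower (test) MSE; ties go to augmentation.
    """
    cfg = config if config is not None else SurrogateConfig()
    aug = augmentation if augmentation is not None else AugmentationConfig(seed=cfg.seed)

    data = prepare_surrogate_data(records, augmentation=aug, config=cfg, leakage=leakage)
    g_means, _ = _repeat_metrics(data, cfg)
    gaussian = FitMetrics(mse=g_means["test_mse"], r2=g_means["test_r2"])

    X, Y = records_to_xy(records)
    input_norm = fit_normalization(X, cfg.input_interval)
    output_norm = fit_normalization(Y, cfg.output_interval)
    Xn, Yn = input_norm.apply(X), output_norm.apply(Y)
    folds = kfold_split(Xn.shape[0], k=k, seed=cfg.seed)
    n_in, n_out = Xn.shape[1], Yn.shape[1]
    mses, r2s, sizes = [], [], []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(Xn.shape[0], dtype=bool)
        train_mask[test_idx] = False
        w, _ = _train_on_normalized(Xn[train_mask], Yn[train_mask], cfg,
                                    seed=cfg.seed * 100003 + 7919 * i)
        P, _ = _forward(w, Xn[test_idx], n_in, cfg.hidden_units, n_out)
        m = evaluate_metrics(P, Yn[test_idx])
        mses.append(m.mse); r2s.append(m.r2); sizes.append(len(test_idx))
    wts = np.asarray(sizes, dtype=float) / sum(sizes)
    cv = FitMetrics(mse=float(np.average(mses, weights=wts)),
                    r2=float(np.average(r2s, weights=wts)))

    winner = "gaussian_noise" if gaussian.mse <= cv.mse else "cross_validation"
    return StrategyComparison(gaussian=gaussian, cross_validation=cv, winner=winner)


def mean_relative_error(model: SurrogateModel,
                        records: Sequence[ExperimentRecord]) -> float:
    """Mean over records and responses of |predicted - true| / |true| (raw scale)."""
    X, Y = records_to_xy(records)
    P = model.predict_array(X)
    return float(np.mean(np.abs(P - Y) / np.abs(Y)))
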