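"""Dissolution-kinetics model fitting and release-parameter extraction.

Six classical models are fitted to a cumulative-release curve, all as
least-squares fits of the release fraction f = cumulative/100 against time
in hours, with R^2 always computed on the untransformed fraction scale:

    zero order        f = k0 * t
    first order       f = 1 - exp(-k1 * t)
    Higuchi           f = kH * sqrt(t)
    Hixson-Crowell    (1 - f)^(1/3) = 1 - kHC * t
    Korsmeyer-Peppas  f = k * t^n        (fitted on f <= 0.6 only)
    Weibull           f = 1 - exp(-t^b / a)

The first-order model uses the fraction form (asymptote 1) because curves
are normalized. The Korsmeyer-Peppas exponent n classifies the transport
mechanism; for a cylindrical matrix n <= 0.45 is Fickian diffusion,
0.45 < n < 0.89 anomalous transport and n >= 0.89 case-II (relaxation
controlled) transport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datamodel import ReleaseCurve
from .exceptions import DomainError, FitError

MODEL_NAMES = ("zero_order", "first_order", "higuchi", "hixson_crowell",
               "korsmeyer_peppas", "weibull")

N_PARAMS = {"zero_order": 1, "first_order": 1, "higuchi": 1,
            "hixson_crowell": 1, "korsmeyer_peppas": 2, "weibull": 2}

#: (n_fickian, n_caseII) thresholds of the Peppas exponent per matrix geometry.
TRANSPORT_THRESHOLDS = {
    "film": (0.50, 1.00),
    "cylinder": (0.45, 0.89),
    "sphere": (0.43, 0.85),
}

PEPPAS_FRACTION_LIMIT = 0.6  # standard validity window of the power law

_CF_KW = dict(ftol=1e-14, xtol=1e-14, gtol=1e-14, maxfev=20000)


def extract_release_params(curve: ReleaseCurve, br_time: float = 0.5):
    """Read (br, trmax, rtrmax) off a cumulative-release curve.

    br is the cumulative release at ``br_time`` hours (linearly interpolated
    between grid points); rtrmax is the maximum cumulative value; trmax is
    the earliest time attaining that maximum, so plateaus resolve to their
    onset.
    """
    t, c = curve.times, curve.cumulative
    if t.max() < br_time:
        raise DomainError(
            f"observation window ({t.max()} h) shorter than br_time={br_time} h")
    br = float(np.interp(br_time, t, c))
    imax = int(np.argmax(c))  # argmax returns the first maximizer
    return br, float(t[imax]), float(c[imax])


@dataclass(frozen=True)
class KineticModelFit:
    """One fitted dissolution model: parameters and goodness of fit."""

    model_name: str
    params: dict
    r_squared: float
    n_obs: int

    def predict_fraction(self, t) -> np.ndarray:
        return _MODEL_FUNCS[self.model_name](np.asarray(t, dtype=float),
                                             *self._theta())

    def _theta(self):
        return tuple(self.params[k] for k in _PARAM_ORDER[self.model_name])

    def summary(self) -> str:
        ps = ", ".join(f"{k}={v:.5g}" for k, v in self.params.items())
        return (f"{self.model_name}: {ps}; R^2 = {self.r_squared:.4f} "
                f"({self.n_obs} points)")


@dataclass(frozen=True)
class TransportClass:
    """Drug-transport mechanism implied by the Peppas exponent."""

    label: str
    geometry: str
    exponent: float


def _f_zero(t, k0):
    return k0 * t


def _f_first(t, k1):
    return 1.0 - np.exp(-k1 * t)


def _f_higuchi(t, kh):
    return kh * np.sqrt(t)


def _f_hixson(t, khc):
    core = np.clip(1.0 - khc * t, 0.0, None)
    return 1.0 - core ** 3


def _f_peppas(t, k, n):
    return k * np.power(t, n)


def _f_weibull(t, a, b):
    return 1.0 - np.exp(-np.power(t, b) / a)


_MODEL_FUNCS = {"zero_order": _f_zero, "first_order": _f_first,
                "higuchi": _f_higuchi, "hixson_crowell": _f_hixson,
                "korsmeyer_peppas": _f_peppas, "weibull": _f_weibull}

_PARAM_ORDER = {"zero_order": ("k0",), "first_order": ("k1",),
                "higuchi": ("kH",), "hixson_crowell": ("kHC",),
                "korsmeyer_peppas": ("k", "n"), "weibull": ("a", "b")}


def _r_squared(f_obs: np.ndarray, f_hat: np.ndarray) -> float:
    ss_res = float(np.sum((f_obs - f_hat) ** 2))
    ss_tot = float(np.sum((f_obs - f_obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _through_origin(x: np.ndarray, f: np.ndarray) -> float:
    denom = float(x @ x)
    if denom == 0.0:
        raise FitError("regressor identically zero")
    return float(x @ f) / denom


def peppas_loglog(curve: ReleaseCurve, fraction_limit: float = PEPPAS_FRACTION_LIMIT):
    """Log-log linear cross-check of the Korsmeyer-Peppas fit.

    Returns (k, n, r2_loglog) from ordinary least squares of ln f on ln t
    over points with 0 < f <= fraction_limit and t > 0.
    """
    t, f = curve.times, curve.cumulative / 100.0
    mask = (t > 0) & (f > 0) & (f <= fraction_limit)
    if mask.sum() < 3:
        raise FitError("need >= 3 positive points with f <= limit for log-log fit")
    lt, lf = np.log(t[mask]), np.log(f[mask])
    n, logk = np.polyfit(lt, lf, 1)
    r2 = _r_squared(lf, n * lt + logk)
    return float(np.exp(logk)), float(n), float(r2)


class KineticModel:
    """Dissolution model bound to a curve; ``fit()`` returns a KineticModelFit."""

    def __init__(self, curve: ReleaseCurve, model: str = "korsmeyer_peppas"):
        if model not in MODEL_NAMES:
            raise DomainError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
        self.curve = curve
        self.model = model

    def _subset(self):
        """Points used by this model's fit."""
        t = self.curve.times
        f = self.curve.cumulative / 100.0
        if self.model == "korsmeyer_peppas":
            mask = (t > 0) & (f <= PEPPAS_FRACTION_LIMIT)
        elif self.model == "weibull":
            mask = t > 0  # d/db t^b undefined at t=0
        else:
            mask = np.ones_like(t, dtype=bool)
        return t[mask], f[mask]

    def fit(self) -> KineticModelFit:
        t, f = self._subset()
        npar = N_PARAMS[self.model]
        if t.size < npar + 1:
            raise FitError(
                f"{self.model}: need >= {npar + 1} usable points, have {t.size}")
        try:
            theta = self._estimate(t, f)
        except FitError:
            raise
        except Exception as exc:  # scipy failure modes vary
            raise FitError(f"{self.model}: fit did not converge ({exc})") from exc
        self._check_params(theta)
        f_hat = _MODEL_FUNCS[self.model](t, *theta)
        r2 = _r_squared(f, f_hat)
        params = dict(zip(_PARAM_ORDER[self.model], (float(x) for x in theta)))
        return KineticModelFit(model_name=self.model, params=params,
                               r_squared=r2, n_obs=int(t.size))

    def _estimate(self, t, f):
        if self.model == "zero_order":
            return (_through_origin(t, f),)
        if self.model == "higuchi":
            return (_through_origin(np.sqrt(t), f),)
        if self.model == "first_order":
            # initial rate of 1-exp(-kt) is k
            pos = t > 0
            k0 = max(np.median(-np.log(np.clip(1 - f[pos], 1e-9, 1)) / t[pos]), 1e-6)
            popt, _ = curve_fit(_f_first, t, f, p0=[k0], **_CF_KW)
            return tuple(popt)
        if self.model == "hixson_crowell":
            g = 1.0 - np.cbrt(np.clip(1.0 - f, 0.0, 1.0))
            k0 = max(_through_origin(t, g), 1e-6)
            popt, _ = curve_fit(_f_hixson, t, f, p0=[k0], **_CF_KW)
            return tuple(popt)
        if self.model == "korsmeyer_peppas":
            try:
                k0, n0, _ = peppas_loglog(self.curve)
            except FitError:
                k0, n0 = 0.3, 0.3
            n0 = min(max(n0, 0.02), 1.4)
            popt, _ = curve_fit(_f_peppas, t, f, p0=[max(k0, 1e-4), n0], **_CF_KW)
            return tuple(popt)
        # weibull
        inner = np.clip(1.0 - f, 1e-9, 1.0)
        w = -np.log(inner)
        mask = w > 1e-9
        if mask.sum() >= 2:
            b0, c0 = np.polyfit(np.log(t[mask]), np.log(w[mask]), 1)
            a0, b0 = float(np.exp(-c0)), float(min(max(b0, 0.02), 5.0))
        else:
            a0, b0 = 30.0, 0.25
        popt, _ = curve_fit(_f_weibull, t, f, p0=[max(a0, 1e-3), b0], **_CF_KW)
        return tuple(popt)

    def _check_params(self, theta) -> None:
        for name, v in zip(_PARAM_ORDER[self.model], theta):
            if not np.isfinite(v) or v <= 0:
                raise FitError(f"{self.model}: parameter {name}={v} not positive")
        if self.model == "korsmeyer_peppas" and not (0 < theta[1] < 1.5):
            raise FitError(f"korsmeyer_peppas: exponent n={theta[1]} outside (0, 1.5)")


def fit_kinetic_model(curve: ReleaseCurve, model_name: str) -> KineticModelFit:
    """Fit one named dissolution model to a curve."""
    return KineticModel(curve, model_name).fit()


@dataclass
class KineticComparison:
    """All successful fits ranked by R^2 (ties to fewer parameters), plus failures."""

    fits: list
    failures: dict = field(default_factory=dict)

    @property
    def best(self) -> KineticModelFit:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model": f.model_name, "r_squared": f.r_squared,
                 "n_params": N_PARAMS[f.model_name], **f.params} for f in self.fits]
        return pd.DataFrame(rows)


def compare_models(curve: ReleaseCurve) -> KineticComparison:
    """Fit all six models; individual failures are recorded, not fatal."""
    fits, failures = [], {}
    for name in MODEL_NAMES:
        try:
            fits.append(fit_kinetic_model(curve, name))
        except FitError as exc:
            failures[name] = str(exc)
    if not fits:
        raise FitError(f"all kinetic fits failed: {failures}")
    fits.sort(key=lambda f: (-f.r_squared, N_PARAMS[f.model_name]))
    return KineticComparison(fits=fits, failures=failures)


def classify_transport(n: float, geometry: str = "cylinder") -> TransportClass:
    """Classify the transport mechanism from the Peppas exponent.

    Boundary values are inclusive toward the adjacent named class:
    n equal to the Fickian threshold is Fickian, n at or above the upper
    threshold is case II.
    """
    if not (n > 0):
        raise DomainError(f"Peppas exponent must be > 0, got {n}")
    if geometry not in TRANSPORT_THRESHOLDS:
        raise DomainError(
            f"unsupported geometry {geometry!r}; choose from {sorted(TRANSPORT_THRESHOLDS)}")
    lo, hi = TRANSPORT_THRESHOLDS[geometry]
    if n <= lo:
        label = "fickian"
    elif n < hi:
        label = "anomalous"
    else:
        label = "case_II"
    return TransportClass(label=label, geometry=geometry, exponent=float(n))
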