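"""Synthetic DOE response datasets with the reported main-effect structure.

The raw release curves of the study are not deposited, so downstream stages
(kinetics fitting, surrogate training, GA optimization) are exercised on
synthetic data generated from a linear main-effects model

    response = baseline + sum_f slope[f] * (x_f - centroid_f) + noise

with Gaussian replicate noise, calibrated to the effect directions and
magnitudes the study reports: over the chitosan span 7.69 -> 25% of sheath
polymer, BR rises ~4 points, TRmax ~28 minutes, RTRmax ~10 points and Le
~17 points; Fe3O4 shifts TRmax by ~16 minutes over 1 -> 5% (default sign
negative, switchable); feeding-ratio effects are positive and modest on
BR/TRmax/RTRmax; drug % and AMF frequency have no effect. Interactions are
not modelled (they are unidentifiable from an L18 anyway).

Cumulative-release curves are power-law (Korsmeyer-Peppas) shapes anchored
to each record's (trmax, rtrmax) so that the release parameters and the
kinetics coefficients stay mutually consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .datamodel import (
    DOEDesign,
    ExperimentRecord,
    FormulationParams,
    ReleaseCurve,
    ReleaseParams,
    records_to_frame,
)
from .exceptions import DomainError, GenerationError

RESPONSES = ("br", "trmax", "rtrmax", "le")
FACTORS = ("feeding_ratio", "cs_percent", "np_percent", "drug_percent",
           "amf_frequency_khz")

#: chitosan span of the design (derived 7.69 -> 25.00 %)
_CS_SPAN = 25.0 - 100.0 * 2.0 / 26.0

#: Loading-efficiency band consistent with the published per-run means.
LE_RANGE = (60.0, 90.0)

#: Default sampling grid, hours; covers every trmax the generator produces.
DEFAULT_TIME_GRID = np.array(
    [0.0, 0.25, 0.5, 1, 2, 4, 8, 12, 24, 36, 48, 72, 96, 120, 144, 168])


def _default_slopes() -> dict:
    return {
        # per unit of feeding ratio (span 1.25 -> 2)
        "feeding_ratio": {"br": 2.5, "trmax": 4.0, "rtrmax": 3.0, "le": 0.0},
        # per chitosan percentage point; calibrated so the full CS span maps
        # to +4 BR points, +28 min TRmax, +10 RTRmax points, +17 Le points
        "cs_percent": {"br": 4.0 / _CS_SPAN, "trmax": (28.0 / 60.0) / _CS_SPAN,
                       "rtrmax": 10.0 / _CS_SPAN, "le": 17.0 / _CS_SPAN},
        # per Fe3O4 percentage point; |16 min| over 1 -> 5%, sign applied
        # separately (see EffectSpec.fe3o4_trmax_sign)
        "np_percent": {"br": 0.0, "trmax": (16.0 / 60.0) / 4.0,
                       "rtrmax": 0.0, "le": 0.0},
        "drug_percent": {"br": 0.0, "trmax": 0.0, "rtrmax": 0.0, "le": 0.0},
        "amf_frequency_khz": {"br": 0.0, "trmax": 0.0, "rtrmax": 0.0, "le": 0.0},
    }


def _default_noise() -> dict:
    return {"br": 1.5, "trmax": 4.0, "rtrmax": 1.5, "le": 1.5}


@dataclass
class EffectSpec:
    """Ground-truth generating model: baseline, slopes, noise, Fe3O4 sign.

    ``baseline`` is the expected response at the design centroid. ``slopes``
    maps factor -> response -> effect per factor unit; the Fe3O4 slope on
    TRmax is stored as a magnitude with its sign in ``fe3o4_trmax_sign``
    (+1 or -1), because the study's two statements about that effect
    disagree in direction.
    """

    baseline: ReleaseParams = field(
        default_factory=lambda: ReleaseParams(br=30.0, trmax=120.0, rtrmax=75.0, le=74.0))
    slopes: dict = field(default_factory=_default_slopes)
    noise_sd: dict = field(default_factory=_default_noise)
    fe3o4_trmax_sign: int = -1

    def __post_init__(self) -> None:
        if self.fe3o4_trmax_sign not in (-1, 1):
            raise DomainError("fe3o4_trmax_sign must be +1 or -1")
        for resp, sd in self.noise_sd.items():
            if sd < 0:
                raise DomainError(f"noise SD for {resp} must be >= 0")

    def slope(self, factor: str, response: str) -> float:
        """Signed effect of ``factor`` on ``response`` per factor unit."""
        s = self.slopes[factor][response]
        if factor == "np_percent" and response == "trmax":
            s = self.fe3o4_trmax_sign * abs(s)
        return s


@dataclass
class SyntheticDataset:
    """Generated records plus the truth that produced them."""

    records: list
    effects: EffectSpec
    seed: int
    replicates: int

    def __post_init__(self) -> None:
        if len(self.records) % self.replicates != 0:
            raise GenerationError("record count is not a multiple of replicates")

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def design_centroid(design: DOEDesign) -> dict:
    """Mean of each structural factor over the 18 runs."""
    frame = design.to_frame()
    return {f: float(frame[f].mean()) for f in FACTORS}


def _mean_response(form: FormulationParams, effects: EffectSpec,
                   centroid: dict) -> dict:
    base = {"br": effects.baseline.br, "trmax": effects.baseline.trmax,
            "rtrmax": effects.baseline.rtrmax, "le": effects.baseline.le}
    out = {}
    for resp in RESPONSES:
        v = base[resp]
        for fac in FACTORS:
            v += effects.slope(fac, resp) * (getattr(form, fac) - centroid[fac])
        out[resp] = v
    return out


def generate_release_curve(response: ReleaseParams, peppas_k: float,
                           peppas_n: float, time_grid: Sequence[float],
                           noise_sd: float = 0.0,
                           rng: Optional[np.random.Generator] = None,
                           seed: Optional[int] = None) -> ReleaseCurve:
    """Power-law cumulative-release curve anchored to (trmax, rtrmax).

    The base shape ``100*k*t^n`` is rescaled to pass through
    ``(response.trmax, response.rtrmax)`` and plateaus at ``rtrmax``
    afterwards. Gaussian noise (SD ``noise_sd``, in release points) is then
    added, the curve is made non-decreasing by isotonic regression, clipped
    to [0, 100], and pinned to 0 at t=0.
    """
    if not (peppas_k > 0):
        raise DomainError(f"peppas_k must be > 0, got {peppas_k}")
    if not (0 < peppas_n < 1):
        raise DomainError(f"peppas_n must be in (0, 1), got {peppas_n}")
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise DomainError("time_grid must be strictly increasing with first >= 0")
    if t.max() < response.trmax:
        raise DomainError(
            f"time_grid (max {t.max()} h) does not cover trmax={response.trmax} h")

    scale = response.rtrmax / (100.0 * peppas_k * response.trmax ** peppas_n)
    y = 100.0 * peppas_k * scale * np.power(t, peppas_n)
    y = np.minimum(y, response.rtrmax)  # plateau after trmax

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
        y = IsotonicRegression(y_min=0.0, y_max=100.0).fit_transform(t, y)
    y = np.clip(y, 0.0, 100.0)
    if t[0] == 0.0:
        y[0] = 0.0
    return ReleaseCurve(times=t, cumulative=y)


def _anchored_peppas_exponent(br: float, trmax: float, rtrmax: float) -> float:
    """Exponent of the anchored power law through (0.5 h, br) and (trmax, rtrmax)."""
    if br <= 0 or br >= rtrmax or trmax <= 0.5:
        return 0.15  # fallback shape for degenerate responses
    n = math.log(br / rtrmax) / math.log(0.5 / trmax)
    return min(max(n, 0.01), 0.99)


def generate_dataset(design: DOEDesign, effects: Optional[EffectSpec] = None,
                     replicates: int = 3, seed: int = 0,
                     with_curves: bool = True, curve_noise_sd: float = 1.0,
                     time_grid: Optional[Sequence[float]] = None) -> SyntheticDataset:
    """Generate ``18 * replicates`` experiment records from the effect model.

    Responses are the linear main-effects means plus Gaussian noise, then
    post-processed to satisfy the physical invariants: Le clipped to
    [60, 90], rtrmax to [0, 100], br to [0, rtrmax], trmax floored at 1 h.
    If a mean response falls grossly outside its band (beyond 10 units of
    clipping), the effect specification is rejected.
    """
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    effects = effects if effects is not None else EffectSpec()
    rng = np.random.default_rng(seed)
    centroid = design_centroid(design)
    grid = np.asarray(DEFAULT_TIME_GRID if time_grid is None else time_grid, dtype=float)

    records: list[ExperimentRecord] = []
    for run in design:
        mean = _mean_response(run.formulation, effects, centroid)
        if (mean["le"] < LE_RANGE[0] - 10 or mean["le"] > LE_RANGE[1] + 10
                or mean["br"] < -10 or mean["rtrmax"] > 110
                or mean["br"] > mean["rtrmax"] + 10 or mean["trmax"] <= 1):
            raise GenerationError(
                f"effect spec drives run {run.code} mean response out of range: {mean}")
        for rep in range(1, replicates + 1):
            vals = {r: mean[r] + rng.normal(0.0, effects.noise_sd[r])
                    if effects.noise_sd[r] > 0 else mean[r] for r in RESPONSES}
            rtrmax = float(np.clip(vals["rtrmax"], 0.0, 100.0))
            br = float(np.clip(vals["br"], 0.0, rtrmax))
            trmax = float(max(vals["trmax"], 1.0))
            le = float(np.clip(vals["le"], *LE_RANGE))
            resp = ReleaseParams(br=br, trmax=trmax, rtrmax=rtrmax, le=le)
            curve = None
            if with_curves:
                n = _anchored_peppas_exponent(br, trmax, rtrmax)
                k = (rtrmax / 100.0) / trmax ** n
                curve = generate_release_curve(
                    resp, k, n, grid, noise_sd=curve_noise_sd, rng=rng)
            records.append(ExperimentRecord(
                run_code=run.code, replicate=rep,
                formulation=run.formulation, response=resp, curve=curve))
    return SyntheticDataset(records=records, effects=effects, seed=seed,
                            replicates=replicates)


def validate_dataset(dataset: SyntheticDataset) -> pd.DataFrame:
    """Main-effects self-check: extreme-level mean differences per factor/response.

    For every factor with at least two observed levels, the difference
    between the highest- and lowest-level response means is reported with
    its standard error; ``significant`` flags |effect| > 2*SE. Single-level
    factors are skipped with a warning. This is a sanity summary of the
    generator, not an inferential analysis.
    """
    frame = dataset.to_frame()
    colmap = {"br": "br_percent", "trmax": "trmax_h",
              "rtrmax": "rtrmax_percent", "le": "le_percent"}
    rows = []
    for fac in FACTORS:
        levels = np.sort(frame[fac].unique())
        if levels.size < 2:
            warnings.warn(f"factor {fac} has a single level; skipped")
            continue
        lo_grp = frame[frame[fac] == levels[0]]
        hi_grp = frame[frame[fac] == levels[-1]]
        for resp in RESPONSES:
            col = colmap[resp]
            effect = hi_grp[col].mean() - lo_grp[col].mean()
            se = math.sqrt(hi_grp[col].var(ddof=1) / len(hi_grp)
                           + lo_grp[col].var(ddof=1) / len(lo_grp))
            rows.append({
                "factor": fac, "response": resp,
                "low_level": levels[0], "high_level": levels[-1],
                "effect": effect, "se": se,
                "significant": bool(abs(effect) > 2 * se) if se > 0 else True,
            })
    return pd.DataFrame(rows)
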