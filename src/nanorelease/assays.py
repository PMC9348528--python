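"""Closed-form assay calculations: magnetic loading, viability, errors, IC50."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ExtrapolationWarning, FitError


@dataclass(frozen=True)
class MagnetizationRecord:
    """Saturation magnetizations (emu/g): pure nanoparticles vs fiber mat."""

    msn: float
    msf: float

    def __post_init__(self):
        if not (self.msn > 0):
            raise DomainError(f"msn={self.msn} must be > 0")
        if not (0 <= self.msf <= self.msn):
            raise DomainError(
                f"msf={self.msf} must lie in [0, msn={self.msn}]; a weight "
                "fraction above 1 is impossible")


@dataclass(frozen=True)
class ViabilityRecord:
    """Mean optical densities of treated wells and the negative control."""

    od_sample: float
    od_control: float

    def __post_init__(self):
        if not (self.od_control > 0):
            raise DomainError(f"od_control={self.od_control} must be > 0")
        if self.od_sample < 0:
            raise DomainError(f"od_sample={self.od_sample} must be >= 0")


def magnetic_fraction(record: MagnetizationRecord) -> float:
    """Weight % of magnetic nanoparticles in the mat: 100 * Msf / Msn.

    The magnetization of the composite scales with the mass fraction of the
    magnetic phase, so the ratio of the mat's saturation magnetization to
    that of the pure nanoparticles is the actual loading.
    """
    return 100.0 * record.msf / record.msn


def viability(record: ViabilityRecord) -> float:
    """Cell viability % relative to the negative control: 100 * ODs / ODc.

    Values above 100% indicate proliferation and are flagged with a warning
    rather than rejected.
    """
    v = 100.0 * record.od_sample / record.od_control
    if v > 100.0:
        warnings.warn(f"viability {v:.1f}% exceeds 100% (proliferation)")
    return v


def relative_error(measured: float, estimated: float) -> float:
    """Relative estimation error %: 100 * |estimated - measured| / |measured|.

    Note the asymmetry: the *measured* value is the denominator.
    """
    if measured == 0:
        raise DomainError("relative error undefined for measured = 0")
    return 100.0 * abs(estimated - measured) / abs(measured)


def ic50_linear(concentrations, viabilities) -> float:
    """IC50 from a linear viability-concentration fit.

    Fits viability = a + b * concentration by least squares and returns the
    concentration at 50% viability, (50 - a) / b. A warning is raised when
    the fitted line is not a decreasing dose-response within the data span.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if c.size != v.size or c.size < 2:
        raise DomainError("need >= 2 (concentration, viability) pairs")
    b, a = np.polyfit(c, v, 1)
    if abs(b) < 1e-12:
        raise FitError("fitted line has zero slope; no 50% crossing")
    ic50 = (50.0 - a) / b
    if b > 0 or not (c.min() <= ic50 <= c.max()):
        warnings.warn(
            "50% crossing lies outside the observed concentration span "
            "(or the slope is not negative); IC50 is an extrapolation",
            ExtrapolationWarning)
    return float(ic50)
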