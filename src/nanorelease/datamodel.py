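"""Domain types and tabular I/O for the core-shell nanofiber release study.

The study varies five structural factors of an electrospun 5FU/Fe3O4
PCL/chitosan core-shell nanofiber over an 18-run Taguchi design:
sheath:core feeding ratio, sheath polymer ratio (PCL:CS), Fe3O4 weight
percent, 5FU weight percent, and alternating-magnetic-field frequency.
Each formulation is summarized by four release responses: burst release
(BR, % released in the first 30 minutes), the time of maximum release
(TRmax, hours), the release percent at that time (RTRmax), and drug
loading efficiency (Le, %).

This module holds the validated dataclasses for those objects, the packaged
design/coefficient tables, and CSV round-tripping for experiment records.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ParseError, SchemaError, ValidationError

_TOL = 1e-9

#: Factor level sets of the printed design.
FEEDING_LEVELS = (1.25, 2.0)
POLYMER_RATIO_LEVELS = ((2, 1), (1, 1), (1, 2))
NP_LEVELS = (1.0, 3.0, 7.0)
DRUG_LEVELS = (1.0, 3.0, 5.0)
FREQUENCY_LEVELS = (0.0, 300.0, 400.0)

#: Default sheath-solution polymer concentrations (wt%): 12% PCL, 2% CS.
PCL_CONCENTRATION = 12.0
CS_CONCENTRATION = 2.0


def cs_percent_from_ratio(
    pcl_parts: float,
    cs_parts: float,
    pcl_conc: float = PCL_CONCENTRATION,
    cs_conc: float = CS_CONCENTRATION,
) -> float:
    """Chitosan mass fraction (%) of total sheath polymer for a volume ratio.

    Mixing ``pcl_parts`` volumes of a ``pcl_conc`` wt% PCL solution with
    ``cs_parts`` volumes of a ``cs_conc`` wt% CS solution gives a CS share of

        100 * cs_parts*cs_conc / (pcl_parts*pcl_conc + cs_parts*cs_conc)

    of the dissolved polymer mass, e.g. 7.69% for 2:1, 14.29% for 1:1 and
    25.00% for 1:2 at the default concentrations.
    """
    for name, v in (("pcl_parts", pcl_parts), ("cs_parts", cs_parts),
                    ("pcl_conc", pcl_conc), ("cs_conc", cs_conc)):
        if not (v > 0):
            raise DomainError(f"{name} must be > 0, got {v!r}")
    cs_mass = cs_parts * cs_conc
    return 100.0 * cs_mass / (pcl_parts * pcl_conc + cs_mass)


@dataclass(frozen=True)
class FormulationParams:
    """Structural description of one formulation (the GA chromosome genes).

    feeding_ratio : sheath:core volumetric feed ratio, in [1, 2]
    cs_percent    : chitosan weight % of sheath polymer mass, in [7, 25]
    np_percent    : Fe3O4 weight %, in [1, 7]
    drug_percent  : 5FU weight %, in [1, 5]
    amf_frequency_khz : AMF frequency in kHz; 0 means no field applied
    """

    feeding_ratio: float
    cs_percent: float
    np_percent: float
    drug_percent: float
    amf_frequency_khz: float = 0.0

    def __post_init__(self) -> None:
        checks = (
            ("feeding_ratio", self.feeding_ratio, 1.0, 2.0),
            ("cs_percent", self.cs_percent, 7.0, 25.0),
            ("np_percent", self.np_percent, 1.0, 7.0),
            ("drug_percent", self.drug_percent, 1.0, 5.0),
        )
        for name, v, lo, hi in checks:
            if not np.isfinite(v) or v < lo - _TOL or v > hi + _TOL:
                raise ValidationError(
                    f"{name}={v!r} outside [{lo}, {hi}]")
        if not np.isfinite(self.amf_frequency_khz) or self.amf_frequency_khz < 0:
            raise ValidationError(
                f"amf_frequency_khz={self.amf_frequency_khz!r} must be >= 0")


@dataclass(frozen=True)
class ReleaseParams:
    """The four release responses the surrogate predicts and the fitness consumes.

    br     : burst release, % released in the first 30 minutes
    trmax  : time of maximum release, hours
    rtrmax : release % at trmax
    le     : drug loading efficiency, %
    """

    br: float
    trmax: float
    rtrmax: float
    le: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.br, self.trmax, self.rtrmax, self.le])):
            raise ValidationError("release parameters must be finite")
        if not (-_TOL <= self.br <= self.rtrmax + _TOL):
            raise ValidationError(
                f"need 0 <= br <= rtrmax, got br={self.br}, rtrmax={self.rtrmax}")
        if self.rtrmax > 100.0 + _TOL:
            raise ValidationError(f"rtrmax={self.rtrmax} exceeds 100%")
        if not (self.trmax > 0):
            raise ValidationError(f"trmax={self.trmax} must be > 0")
        if not (0 < self.le <= 100.0 + _TOL):
            raise ValidationError(f"le={self.le} must be in (0, 100]")


@dataclass(frozen=True)
class ReleaseCurve:
    """Cumulative-release time series: % of loaded drug released vs hours."""

    times: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cumulative, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative", c)
        if t.ndim != 1 or t.shape != c.shape or t.size < 2:
            raise ValidationError("times/cumulative must be equal-length 1-d arrays (>= 2 points)")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise ValidationError("curve contains non-finite values")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing with first >= 0")
        if c.min() < -_TOL or c.max() > 100.0 + _TOL:
            raise ValidationError("cumulative values must lie in [0, 100]")
        if np.any(np.diff(c) < -_TOL):
            raise ValidationError("cumulative release must be non-decreasing")
        if t[0] == 0.0 and abs(c[0]) > _TOL:
            raise ValidationError("cumulative release at t=0 must be 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ExperimentRecord:
    """One replicate of one design run: formulation, responses, optional curve."""

    run_code: str
    replicate: int
    formulation: FormulationParams
    response: ReleaseParams
    curve: Optional[ReleaseCurve] = None

    def __post_init__(self) -> None:
        # the study ran 3 replicates; Monte-Carlo self-checks may run more
        if not (isinstance(self.replicate, (int, np.integer)) and self.replicate >= 1):
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate}")


@dataclass(frozen=True)
class DOERun:
    """One labeled run of the design, with the sheath ratio in volume parts."""

    code: str
    pcl_parts: int
    cs_parts: int
    formulation: FormulationParams


@dataclass(frozen=True)
class DOEDesign:
    """The ordered 18-run design (codes C1..C18)."""

    runs: tuple

    def __post_init__(self) -> None:
        if len(self.runs) != 18:
            raise ValidationError(f"design must have exactly 18 runs, got {len(self.runs)}")
        expected = [f"C{i}" for i in range(1, 19)]
        codes = [r.code for r in self.runs]
        if codes != expected:
            raise ValidationError(f"run codes must be C1..C18 in order, got {codes}")
        for r in self.runs:
            f = r.formulation
            if f.feeding_ratio not in FEEDING_LEVELS:
                raise ValidationError(f"{r.code}: feeding_ratio {f.feeding_ratio} not a design level")
            if (r.pcl_parts, r.cs_parts) not in POLYMER_RATIO_LEVELS:
                raise ValidationError(f"{r.code}: ratio {r.pcl_parts}:{r.cs_parts} not a design level")
            if f.np_percent not in NP_LEVELS:
                raise ValidationError(f"{r.code}: np_percent {f.np_percent} not a design level")
            if f.drug_percent not in DRUG_LEVELS:
                raise ValidationError(f"{r.code}: drug_percent {f.drug_percent} not a design level")
            if f.amf_frequency_khz not in FREQUENCY_LEVELS:
                raise ValidationError(f"{r.code}: frequency {f.amf_frequency_khz} not a design level")

    def __iter__(self) -> Iterator[DOERun]:
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)

    def run(self, code: str) -> DOERun:
        for r in self.runs:
            if r.code == code:
                return r
        raise KeyError(code)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.runs:
            f = r.formulation
            rows.append({
                "run_code": r.code,
                "feeding_ratio": f.feeding_ratio,
                "pcl_parts": r.pcl_parts,
                "cs_parts": r.cs_parts,
                "cs_percent": f.cs_percent,
                "np_percent": f.np_percent,
                "drug_percent": f.drug_percent,
                "amf_frequency_khz": f.amf_frequency_khz,
            })
        return pd.DataFrame(rows)


_DESIGN_KEYS = ("code", "feeding_ratio", "pcl_parts", "cs_parts",
                "np_percent", "drug_percent", "amf_frequency_khz")


def _run_from_mapping(row: dict) -> DOERun:
    code = str(row.get("code", "<unknown>"))
    try:
        pcl = int(row["pcl_parts"])
        cs = int(row["cs_parts"])
        form = FormulationParams(
            feeding_ratio=float(row["feeding_ratio"]),
            cs_percent=cs_percent_from_ratio(pcl, cs),
            np_percent=float(row["np_percent"]),
            drug_percent=float(row["drug_percent"]),
            amf_frequency_khz=float(row["amf_frequency_khz"]),
        )
    except ValidationError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed design row for run {code}: {exc}") from exc
    return DOERun(code=code, pcl_parts=pcl, cs_parts=cs, formulation=form)


def load_doe_design(source: Optional[str | Path] = None) -> DOEDesign:
    """Load the 18-run design, from the packaged table by default.

    ``source`` may be a path to a JSON file with a ``runs`` list or a CSV
    with columns matching the packaged fixture. The derived ``cs_percent``
    of each run is attached from its PCL:CS volume parts.
    """
    if source is None:
        payload = json.loads(
            resources.files("nanorelease.fixtures").joinpath("doe_design.json").read_text())
        rows = payload["runs"]
    else:
        path = Path(source)
        if not path.exists():
            raise SchemaError(f"design source {path} does not exist")
        if path.suffix.lower() == ".json":
            rows = json.loads(path.read_text())["runs"]
        else:
            frame = pd.read_csv(path, float_precision="round_trip")
            missing = set(_DESIGN_KEYS) - set(frame.columns)
            if missing:
                raise SchemaError(f"design table missing columns: {sorted(missing)}")
            rows = frame.to_dict("records")
    return DOEDesign(runs=tuple(_run_from_mapping(r) for r in rows))


def load_loading_kinetics_table() -> pd.DataFrame:
    """Published per-run loading efficiencies and kinetic-model coefficients."""
    payload = json.loads(
        resources.files("nanorelease.fixtures").joinpath("loading_kinetics.json").read_text())
    rows = []
    for r in payload["runs"]:
        rows.append({
            "run_code": r["code"],
            "drug_theoretical_percent": r["drug_theoretical_percent"],
            "le_mean": r["le_mean"], "le_sd": r["le_sd"],
            "peppas_k": r["peppas"]["k"], "peppas_n": r["peppas"]["n"],
            "peppas_r2": r["peppas"]["r2"],
            "weibull_a": r["weibull"]["a"], "weibull_b": r["weibull"]["b"],
            "weibull_r2": r["weibull"]["r2"],
        })
    return pd.DataFrame(rows)


def load_optimized_release_table() -> dict:
    """Published release parameters, ANN estimates and errors for the optimized formulation."""
    return json.loads(
        resources.files("nanorelease.fixtures").joinpath("optimized_release.json").read_text())


# ---------------------------------------------------------------------------
# Experiment-record tables
# ---------------------------------------------------------------------------

RECORD_COLUMNS = (
    "run_code", "replicate", "feeding_ratio", "cs_percent", "np_percent",
    "drug_percent", "amf_frequency_khz",
    "br_percent", "trmax_h", "rtrmax_percent", "le_percent",
)

CURVE_COLUMNS = ("run_code", "replicate", "time_h", "cumulative_percent")


def records_to_frame(records: Iterable[ExperimentRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        f, y = rec.formulation, rec.response
        rows.append({
            "run_code": rec.run_code, "replicate": rec.replicate,
            "feeding_ratio": f.feeding_ratio, "cs_percent": f.cs_percent,
            "np_percent": f.np_percent, "drug_percent": f.drug_percent,
            "amf_frequency_khz": f.amf_frequency_khz,
            "br_percent": y.br, "trmax_h": y.trmax,
            "rtrmax_percent": y.rtrmax, "le_percent": y.le,
        })
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def write_records(records: Sequence[ExperimentRecord], path: str | Path,
                  curves_path: Optional[str | Path] = None) -> None:
    """Write records to CSV (one row per replicate); optionally the curves too.

    Floats are written with 17 significant digits so a write/read round trip
    preserves every field bit-for-bit.
    """
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
    if curves_path is not None:
        rows = []
        for rec in records:
            if rec.curve is None:
                continue
            for t, c in zip(rec.curve.times, rec.curve.cumulative):
                rows.append({"run_code": rec.run_code, "replicate": rec.replicate,
                             "time_h": t, "cumulative_percent": c})
        pd.DataFrame(rows, columns=list(CURVE_COLUMNS)).to_csv(
            curves_path, index=False, float_format="%.17g")


def read_records(path: str | Path,
                 curves_path: Optional[str | Path] = None) -> list[ExperimentRecord]:
    """Read experiment records (and optionally their curves) from CSV."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"records table missing columns: {sorted(missing)}")

    curves: dict[tuple[str, int], ReleaseCurve] = {}
    if curves_path is not None:
        cframe = pd.read_csv(curves_path, float_precision="round_trip")
        cmissing = set(CURVE_COLUMNS) - set(cframe.columns)
        if cmissing:
            raise SchemaError(f"curves table missing columns: {sorted(cmissing)}")
        for (code, rep), grp in cframe.groupby(["run_code", "replicate"], sort=False):
            curves[(str(code), int(rep))] = ReleaseCurve(
                times=grp["time_h"].to_numpy(), cumulative=grp["cumulative_percent"].to_numpy())

    records: list[ExperimentRecord] = []
    bad: list[str] = []
    for _, row in frame.iterrows():
        key = (str(row["run_code"]), int(row["replicate"]))
        try:
            records.append(ExperimentRecord(
                run_code=key[0], replicate=key[1],
                formulation=FormulationParams(
                    feeding_ratio=float(row["feeding_ratio"]),
                    cs_percent=float(row["cs_percent"]),
                    np_percent=float(row["np_percent"]),
                    drug_percent=float(row["drug_percent"]),
                    amf_frequency_khz=float(row["amf_frequency_khz"])),
                response=ReleaseParams(
                    br=float(row["br_percent"]), trmax=float(row["trmax_h"]),
                    rtrmax=float(row["rtrmax_percent"]), le=float(row["le_percent"])),
                curve=curves.get(key),
            ))
        except ValidationError as exc:
            bad.append(f"{key[0]} rep {key[1]}: {exc}")
    if bad:
        raise ValidationError(
            "invalid records: " + "; ".join(bad))
    return records
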