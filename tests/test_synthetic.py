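import numpy as np
import pandas as pd
import pytest

import nanorelease as nr
from nanorelease.datamodel import ReleaseParams, records_to_frame
from nanorelease.exceptions import DomainError, GenerationError
from nanorelease.kinetics import extract_release_params
from nanorelease.synthetic import (
    EffectSpec,
    generate_dataset,
    generate_release_curve,
    validate_dataset,
)

ZERO_NOISE = {"br": 0.0, "trmax": 0.0, "rtrmax": 0.0, "le": 0.0}


class TestGenerateDataset:
    def test_default_yields_54_records(self, default_dataset):
        assert len(default_dataset.records) == 54

    def test_zero_noise_replicates_identical(self, design):
        spec = EffectSpec(noise_sd=ZERO_NOISE)
        ds = generate_dataset(design, effects=spec, seed=3, with_curves=False)
        frame = ds.to_frame().drop(columns="replicate")
        per_run = frame.groupby("run_code").nunique()
        assert (per_run == 1).all().all()

    def test_same_seed_bit_identical(self, design, tmp_path):
        for i, name in enumerate(("a.csv", "b.csv")):
            ds = generate_dataset(design, seed=11)
            nr.write_records(ds.records, tmp_path / name,
                             curves_path=tmp_path / f"c{i}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "c0.csv").read_bytes() == (tmp_path / "c1.csv").read_bytes()

    def test_records_satisfy_invariants(self, default_dataset):
        frame = default_dataset.to_frame()
        assert (frame["br_percent"] <= frame["rtrmax_percent"]).all()
        assert frame["le_percent"].between(60, 90).all()

    def test_effect_recovery_at_200_replicates(self, design):
        """OLS slope of Le on CS% converges to the injected 17/(25-7.69)."""
        ds = generate_dataset(design, replicates=200, seed=5, with_curves=False)
        frame = ds.to_frame()
        slope = np.polyfit(frame["cs_percent"], frame["le_percent"], 1)[0]
        injected = ds.effects.slope("cs_percent", "le")
        assert injected == pytest.approx(17.0 / (25.0 - 7.69), rel=0.01)
        assert slope == pytest.approx(injected, rel=0.05)

    def test_absurd_effects_rejected(self, design):
        spec = EffectSpec(baseline=ReleaseParams(br=30, trmax=120, rtrmax=75, le=99))
        with pytest.raises(GenerationError):
            generate_dataset(design, effects=spec, seed=0)


class TestGenerateReleaseCurve:
    GRID = np.array([0.0, 0.25, 0.5, 1, 2, 4, 8, 24, 48, 96, 144])

    def test_anchored_power_law_values(self):
        """Anchoring reproduces 100*k*t^n at the anchor and at 30 minutes."""
        rp = ReleaseParams(br=38.38, trmax=144.0, rtrmax=80.15, le=81.0)
        curve = generate_release_curve(rp, 0.42, 0.13, self.GRID, noise_sd=0.0)
        assert curve.cumulative[-1] == pytest.approx(80.15, abs=1e-9)
        assert float(np.interp(0.5, curve.times, curve.cumulative)) == pytest.approx(
            38.38, abs=0.01)

    def test_noiseless_curve_is_monotone_with_zero_start(self):
        rp = ReleaseParams(br=30, trmax=96, rtrmax=75, le=70)
        curve = generate_release_curve(rp, 0.35, 0.15, self.GRID)
        assert curve.cumulative[0] == 0.0
        assert np.all(np.diff(curve.cumulative) >= 0)

    def test_extraction_closure(self):
        """extract(generate(rp)) returns the generating release parameters."""
        rp = ReleaseParams(br=28.0, trmax=96.0, rtrmax=72.0, le=70.0)
        n = np.log(rp.br / rp.rtrmax) / np.log(0.5 / rp.trmax)
        k = (rp.rtrmax / 100) / rp.trmax ** n
        curve = generate_release_curve(rp, k, n, self.GRID, noise_sd=0.0)
        br, trmax, rtrmax = extract_release_params(curve)
        assert br == pytest.approx(rp.br, abs=1e-9)
        assert trmax == pytest.approx(rp.trmax, abs=1e-9)
        assert rtrmax == pytest.approx(rp.rtrmax, abs=1e-9)

    def test_noisy_closure_within_tolerance(self):
        rp = ReleaseParams(br=28.0, trmax=96.0, rtrmax=72.0, le=70.0)
        n = np.log(rp.br / rp.rtrmax) / np.log(0.5 / rp.trmax)
        k = (rp.rtrmax / 100) / rp.trmax ** n
        grid = np.concatenate([[0, 0.25, 0.5, 1, 2, 4], np.linspace(8, 144, 60)])
        curve = generate_release_curve(rp, k, n, grid, noise_sd=1.0, seed=4)
        br, _, rtrmax = extract_release_params(curve)
        assert br == pytest.approx(rp.br, abs=3.0)
        assert rtrmax == pytest.approx(rp.rtrmax, abs=3.0)

    def test_grid_not_covering_trmax_rejected(self):
        rp = ReleaseParams(br=30, trmax=200, rtrmax=75, le=70)
        with pytest.raises(DomainError):
            generate_release_curve(rp, 0.4, 0.15, self.GRID)


class TestValidateDataset:
    def test_cs_flagged_for_all_responses(self, design):
        # the CS->TRmax effect is only 28 min against a 4 h replicate SD, so
        # detecting all four responses takes a few hundred replicates
        ds = generate_dataset(design, replicates=400, seed=9, with_curves=False)
        summary = validate_dataset(ds)
        cs = summary[summary["factor"] == "cs_percent"]
        assert cs["significant"].all()

    def test_null_factors_flagged_at_nominal_rate_only(self, design):
        """AMF frequency and drug % carry no injected effect, so their flag
        rate should stay near the ~5% false-positive rate of the 2*SE rule."""
        rates = []
        for seed in range(5):
            ds = generate_dataset(design, seed=seed, with_curves=False)
            summary = validate_dataset(ds)
            nulls = summary[summary["factor"].isin(
                ["amf_frequency_khz", "drug_percent"])]
            rates.append(nulls["significant"].mean())
        assert np.mean(rates) < 0.25

    def test_null_effects_rarely_flagged(self, design):
        """With all effects zeroed, flags should stay near the nominal ~5% rate."""
        spec = EffectSpec(slopes={f: {r: 0.0 for r in ("br", "trmax", "rtrmax", "le")}
                                  for f in ("feeding_ratio", "cs_percent", "np_percent",
                                            "drug_percent", "amf_frequency_khz")})
        flags = []
        for seed in range(5):
            ds = generate_dataset(design, effects=spec, seed=seed, with_curves=False)
            flags.append(validate_dataset(ds)["significant"].mean())
        assert np.mean(flags) < 0.25

    def test_fe3o4_trmax_sign_switch(self, design):
        effects = {}
        for sign in (-1, 1):
            spec = EffectSpec(noise_sd=ZERO_NOISE, fe3o4_trmax_sign=sign)
            ds = generate_dataset(design, effects=spec, seed=0, with_curves=False)
            row = validate_dataset(ds).query(
                "factor == 'np_percent' and response == 'trmax'")
            effects[sign] = float(row["effect"].iloc[0])
        assert effects[-1] < 0 < effects[1]
        assert effects[1] == pytest.approx(-effects[-1])
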