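"""Closed-form model: components, limits, stability, and monotonicity."""

import numpy as np
import pytest
from _oracles import scaled_erfc_oracle

from cuaging import (
    ModelParams,
    SoilSample,
    arrhenius_k,
    diffusion_survival,
    hydroxide_fraction,
    occlusion_fraction,
    precipitation_fraction,
    predict_components,
)
from cuaging.model import _predict_arrays, kinetic_factor


class TestHydroxideFraction:
    def test_half_at_pk0(self):
        assert hydroxide_fraction(7.7, 7.7) == pytest.approx(0.5)

    def test_reference_value(self):
        # 1/(10^(7.7-5.43) + 1), frozen from direct high-precision evaluation
        assert hydroxide_fraction(5.43, 7.7) == pytest.approx(5.341631703012352e-3, rel=1e-12)

    def test_acid_limit_vanishes(self):
        assert hydroxide_fraction(0.0, 10.0) == pytest.approx(1e-10, rel=1e-6)

    def test_strictly_increasing_in_ph(self, rng):
        ph = np.sort(rng.uniform(0, 14, 50))
        vals = hydroxide_fraction(ph, 7.7)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))


class TestFastProcesses:
    def test_precipitation_zero_when_b_zero(self, hygum1):
        assert precipitation_fraction(hygum1, ModelParams(b=0.0)) == 0.0

    def test_precipitation_reference(self, hygum1):
        # 1.14 * hydroxide_fraction(5.43, 7.7), frozen
        p = ModelParams(b=1.14, c=0.0)
        assert precipitation_fraction(hygum1, p) == pytest.approx(6.08946014143408e-3, rel=1e-12)

    def test_c_zero_time_independent(self):
        p = ModelParams()
        s1 = SoilSample("a", 6.0, 2.0, 290.0, 10.0)
        s2 = SoilSample("a", 6.0, 2.0, 290.0, 5000.0)
        assert precipitation_fraction(s1, p) == precipitation_fraction(s2, p)

    def test_occlusion_linear_in_corg(self):
        p = ModelParams(f=2.85, g=0.0)
        lo = SoilSample("lo", 5.0, 2.58, 290.0, 30.0)
        hi = SoilSample("hi", 5.0, 23.32, 290.0, 30.0)
        assert occlusion_fraction(lo, p) == pytest.approx(0.073530, abs=1e-12)
        assert occlusion_fraction(hi, p) == pytest.approx(0.66462, rel=1e-10)
        zero = SoilSample("z", 5.0, 0.0, 290.0, 30.0)
        assert occlusion_fraction(zero, p) == 0.0

    @pytest.mark.parametrize("t,c,expected", [(10.0, 0.0, 1.0), (0.0, 0.0, 1.0), (0.0, 2.0, 0.0)])
    def test_kinetic_factor_degenerate_cases(self, t, c, expected):
        assert kinetic_factor(t, c) == expected


class TestDiffusionSurvival:
    def test_unity_at_time_zero(self):
        s = SoilSample("t0", 5.0, 2.0, 290.0, 0.0)
        assert diffusion_survival(s, ModelParams()) == 1.0

    @pytest.mark.parametrize(
        "temp,days,expected",
        [
            (288.0, 28470.0, 0.3489947503985956),  # x ~ 1.808 (78-year field soil)
            (293.0, 360.0, 0.8321662565683078),  # x ~ 0.0295 (1-year incubation)
        ],
    )
    def test_frozen_oracle_values(self, temp, days, expected):
        s = SoilSample("s", 5.0, 2.0, temp, days)
        assert diffusion_survival(s, ModelParams()) == pytest.approx(expected, rel=1e-9)

    def test_matches_quadrature_oracle_on_log_grid(self):
        for x in np.logspace(-8, 4, 49):
            s = SoilSample("s", 5.0, 2.0, 290.0, 1.0)
            p = ModelParams(n=x * np.exp(4330.0 / 290.0))  # makes x = N e^{K/T} t
            assert diffusion_survival(s, p) == pytest.approx(scaled_erfc_oracle(x), rel=1e-9)

    def test_no_overflow_at_huge_argument(self):
        s = SoilSample("s", 5.0, 2.0, 290.0, 1e12)
        p = ModelParams(n=1e8)
        val = diffusion_survival(s, p)
        assert 0.0 < val < 1e-3 and np.isfinite(val)

    def test_short_time_sqrt_limit(self):
        # diffusion loss 1 - S(x) -> 2*sqrt(x/pi), the sqrt(t) regime
        for x in np.logspace(-8, -4, 9):
            loss = 1.0 - scaled_erfc_oracle(x)
            ref = 2.0 * np.sqrt(x / np.pi)
            assert abs(loss - ref) / ref < 0.01

    def test_long_time_power_law_limit(self):
        for x in np.logspace(2, 6, 9):
            s_val = scaled_erfc_oracle(x)
            assert abs(s_val - 1.0 / np.sqrt(np.pi * x)) / s_val < 0.01


class TestPredictEAdd:
    def test_hygum1_field_prediction(self, hygum1, published_params):
        comp = predict_components(hygum1, published_params)
        assert comp.e_add == pytest.approx(0.3212, abs=5e-4)
        assert not comp.clamped

    def test_unaged_soil_fully_labile(self, published_params):
        s = SoilSample("fresh", 7.0, 10.0, 290.0, 0.0)
        assert predict_components(s, published_params).e_add == 1.0

    def test_all_channels_off_gives_unity(self):
        p = ModelParams(b=0.0, f=0.0, n=0.0)
        s = SoilSample("inert", 7.0, 10.0, 290.0, 5000.0)
        assert predict_components(s, p).e_add == 1.0

    def test_decomposition_identity(self, rng):
        # survival-form prediction equals the additive 1 - Y1 - Y2 - Y3 form
        p = ModelParams()
        for _ in range(200):
            s = SoilSample(
                "s",
                rng.uniform(2.98, 7.0),
                rng.uniform(0.41, 10.0),
                rng.uniform(278, 298),
                rng.uniform(1, 30000),
            )
            comp = predict_components(s, p)
            additive = 1.0 - comp.y1 - comp.y2 - comp.y3
            assert comp.e_add == pytest.approx(additive, rel=1e-12)

    def test_monotone_nonincreasing_in_each_covariate(self, rng):
        p = ModelParams()  # C = G = 0
        for _ in range(20):
            base = dict(
                ph=rng.uniform(3, 7.5),
                corg=rng.uniform(0.4, 20),
                temperature=rng.uniform(278, 298),
                time=rng.uniform(1, 30000),
            )
            for var, grid in [
                ("time", np.sort(rng.uniform(1, 30000, 8))),
                ("temperature", np.sort(rng.uniform(278, 298, 8))),
                ("ph", np.sort(rng.uniform(2.98, 7.52, 8))),
                ("corg", np.sort(rng.uniform(0.41, 23.32, 8))),
            ]:
                vals = []
                for v in grid:
                    cov = dict(base, **{var: v})
                    vals.append(predict_components(SoilSample("s", **cov), p).e_add)
                assert np.all(np.diff(vals) <= 1e-15), f"not non-increasing in {var}"

    def test_bounds_and_clamping(self, rng):
        p = ModelParams()
        s = SoilSample("peat", 7.5, 23.32, 288.0, 100.0)  # Y1 + Y2 > 1
        comp = predict_components(s, p)
        assert comp.clamped and comp.e_add == 0.0
        ph, corg, temp, t = (
            rng.uniform(0, 14, 500),
            rng.uniform(0, 30, 500),
            rng.uniform(250, 330, 500),
            rng.uniform(0, 1e5, 500),
        )
        _, _, _, e_add, _ = _predict_arrays(ph, corg, temp, t, p)
        assert np.all((e_add >= 0.0) & (e_add <= 1.0))


def test_arrhenius_composite_for_36_kj_per_mol():
    # Ea = 36 kJ/mol -> K = -Ea/R = -4330 K to the nearest integer
    assert round(arrhenius_k(36_000.0)) == -4330


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(ph=-0.1, corg=1.0, temperature=290.0, time=1.0),
        dict(ph=5.0, corg=-1.0, temperature=290.0, time=1.0),
        dict(ph=5.0, corg=1.0, temperature=0.0, time=1.0),
        dict(ph=5.0, corg=1.0, temperature=290.0, time=-1.0),
    ],
)
def test_sample_invariants_enforced(kwargs):
    with pytest.raises(ValueError):
        SoilSample("bad", **kwargs)


def test_params_invariants_enforced():
    with pytest.raises(ValueError):
        ModelParams(b=-0.1)
    with pytest.raises(ValueError):
        ModelParams(k=5.0)
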