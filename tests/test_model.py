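"""Unit and property tests for the core model module."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltmir import (
    DIALECTS,
    ModelParameters,
    ModelState,
    PHB_1D,
    SaltProtocol,
    WILD_TYPE,
    genotype_from_name,
    hill_activation,
    production_terms,
    rhs,
)
from saltmir.model import ConfigError


class TestHillActivation:
    def test_zero_input(self):
        assert hill_activation(0.0, 0.5, 1.0) == 0.0

    def test_half_saturation(self):
        assert hill_activation(0.5, 0.5, 1.0) == pytest.approx(0.5, abs=1e-15)

    def test_direct_evaluation(self):
        # 1 / (0.4 + 1) = 1 / 1.4
        assert hill_activation(1.0, 0.4, 1.0) == pytest.approx(1.0 / 1.4, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(-0.1, 0.5, 1.0)

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(1.0, 0.0, 1.0)

    @given(
        x1=st.floats(0.0, 5.0),
        dx=st.floats(0.01, 5.0),
        K=st.floats(0.2, 5.0),
        n=st.floats(1.0, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_and_bounded(self, x1, dx, K, n):
        # ranges keep the increments above float rounding near saturation
        lo, hi = hill_activation(x1, K, n), hill_activation(x1 + dx, K, n)
        assert 0.0 <= lo < hi < 1.0

    def test_saturates_to_one(self):
        assert hill_activation(1e9, 0.5, 1.0) == pytest.approx(1.0, abs=1e-8)


class TestProductionTerms:
    @pytest.mark.parametrize("dialect", ["multiplicative", "subtractive_clamped"])
    def test_zero_state(self, dialect):
        p = ModelParameters(dialect=dialect)
        assert production_terms(ModelState(0, 0, 0), p, 0.0) == (1.0, 1.0, 1.0)

    def test_unit_state_multiplicative(self, params):
        ck, phb, mir = production_terms(ModelState(1, 1, 1), params, 0.0)
        assert ck == pytest.approx(1.6667, abs=5e-5)
        assert phb == pytest.approx(0.2857, abs=5e-5)
        assert mir == pytest.approx(0.2857, abs=5e-5)

    def test_multiplicative_equals_subtractive_at_defaults(self):
        # alphaPHB == betaPHB1 and alphamiR == betamiR1 make the two
        # repression forms algebraically identical: a - a*h = a*(1 - h)
        pm = ModelParameters(dialect="multiplicative")
        ps = ModelParameters(dialect="subtractive_clamped")
        for ck in np.linspace(0.0, 10.0, 41):
            state = ModelState(ck, 0.7, 0.3)
            m = production_terms(state, pm, 0.0)
            s = production_terms(state, ps, 0.0)
            assert m == pytest.approx(s, abs=1e-14)

    def test_literal_plus_matches_formula(self):
        p = ModelParameters(dialect="literal_plus")
        ck = 1.3
        _, phb, mir = production_terms(ModelState(ck, 1, 1), p, 0.25)
        assert phb == pytest.approx(1.0 - 1.0 / (1.0 + ck / 0.4), abs=1e-14)
        assert mir == pytest.approx(1.0 / 1.25 - 1.0 / (1.0 + ck / 0.4), abs=1e-14)

    @pytest.mark.parametrize("dialect", ["multiplicative", "subtractive_clamped"])
    def test_nonnegative_productions(self, dialect):
        p = ModelParameters(dialect=dialect, betaPHB1=3.0, betamiR1=3.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            state = ModelState(*rng.uniform(0, 5, size=3))
            for term in production_terms(state, p, rng.uniform(0, 10)):
                assert term >= 0.0

    def test_monotone_in_salt(self):
        # miR production decreasing in salt in every dialect; strictly so
        # wherever the clamped form has not bottomed out at zero
        for dialect in DIALECTS:
            p = ModelParameters(dialect=dialect)
            state = ModelState(0.8, 0.5, 0.2)
            salts = np.linspace(0.0, 10.0, 21)
            mir = [production_terms(state, p, s)[2] for s in salts]
            assert all(b <= a for a, b in zip(mir, mir[1:]))
            assert all(b < a for a, b in zip(mir, mir[1:]) if a > 0)

    def test_negative_salt_rejected(self, params):
        with pytest.raises(ValueError):
            production_terms(ModelState(1, 1, 1), params, -0.1)

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ConfigError):
            ModelParameters(dialect="nope")


class TestRhs:
    def test_unit_state_wild_type(self, params):
        d = rhs(ModelState(1, 1, 1), params, 0.0, WILD_TYPE)
        assert d == pytest.approx([0.6667, 0.2857 - 2.0, 0.2857 - 1.0], abs=5e-5)

    def test_unit_state_phb_1d(self, params):
        d = rhs(ModelState(1, 1, 1), params, 0.0, PHB_1D)
        assert d[1] == pytest.approx(0.2857 - 1.0, abs=5e-5)

    def test_pure_decay_limit(self):
        p = ModelParameters(alphaCK=0.0, betaCK1=0.0, dCK=0.7)
        for c in (0.0, 0.5, 3.0):
            d = rhs(ModelState(c, 1, 1), p, 0.0)
            assert d[0] == pytest.approx(-0.7 * c, abs=1e-14)

    @given(
        ck=st.floats(0.0, 10.0),
        phb=st.floats(0.0, 10.0),
        mir=st.floats(0.0, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_dialect_agreement_at_salt_zero(self, ck, phb, mir):
        state = ModelState(ck, phb, mir)
        dm = rhs(state, ModelParameters(dialect="multiplicative"), 0.0)
        ds = rhs(state, ModelParameters(dialect="subtractive_clamped"), 0.0)
        assert np.max(np.abs(dm - ds)) < 1e-12

    def test_phb_1d_independent_of_mir_and_salt(self, params):
        # PHB component must not respond to miR166; CK and PHB components
        # must not respond to salt (finite differences exactly zero).
        s0 = ModelState(1.1, 0.6, 0.3)
        s1 = ModelState(1.1, 0.6, 0.9)
        d0 = rhs(s0, params, 0.0, PHB_1D)
        d1 = rhs(s1, params, 0.0, PHB_1D)
        assert d1[1] - d0[1] == 0.0
        d2 = rhs(s0, params, 5.0, PHB_1D)
        assert d2[0] - d0[0] == 0.0
        assert d2[1] - d0[1] == 0.0

    def test_derivative_nonnegative_at_zero_boundary(self):
        # each component's derivative at 0 is >= 0 under the default dialect
        rng = np.random.default_rng(1)
        p = ModelParameters()
        for _ in range(30):
            other = rng.uniform(0, 5, size=2)
            assert rhs(ModelState(0, *other), p, 1.0)[0] >= 0
            assert rhs(ModelState(other[0], 0, other[1]), p, 1.0)[1] >= 0
            assert rhs(ModelState(*other, 0), p, 1.0)[2] >= 0


class TestModelParameters:
    def test_defaults_reproduce_published_table(self, params):
        assert params.betaCK2 == 0.5
        assert params.betaPHB2 == 0.4
        assert params.betamiR2 == 0.4
        assert params.n == 1.0
        for name in ("alphaCK", "betaCK1", "dCK", "alphaPHB", "betaPHB1",
                     "dPHB", "dPHBmiR", "alphamiR", "betamiR1", "dmiR"):
            assert getattr(params, name) == 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alphaCK": -0.1},
            {"betaCK2": 0.0},
            {"dCK": 0.0},
            {"dmiR": 0.0},
            {"n": 0.5},
            {"alphamiR": float("nan")},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises((ConfigError, ValueError)):
            ModelParameters(**kwargs)

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ConfigError):
            ModelParameters.from_dict({"alphaCK": 1.0, "bogus": 2.0})

    def test_from_file_roundtrip(self, tmp_path):
        cfg = tmp_path / "params.yaml"
        cfg.write_text("alphaCK: 2.0\nbetaCK2: 0.25\ndialect: subtractive_clamped\n")
        p = ModelParameters.from_file(cfg)
        assert p.alphaCK == 2.0
        assert p.betaCK2 == 0.25
        assert p.dialect == "subtractive_clamped"
        assert p.dPHB == 1.0  # untouched default


class TestGenotype:
    def test_presets(self):
        assert genotype_from_name("wild_type").dPHBmiR_multiplier == 1.0
        assert genotype_from_name("phb_1d").dPHBmiR_multiplier == 0.0

    def test_unknown_name(self):
        with pytest.raises(ConfigError):
            genotype_from_name("superman")


class TestSaltProtocol:
    def test_constant_and_step(self):
        c = SaltProtocol.constant(0.5)
        assert c.salt_at(0.0) == 0.5
        assert c.salt_at(100.0) == 0.5
        s = SaltProtocol.step(0.5, at_time=10.0)
        assert s.salt_at(9.999) == 0.0
        assert s.salt_at(10.0) == 0.5

    def test_intervals_cover_horizon(self):
        s = SaltProtocol(((0.0, 0.0), (10.0, 0.5), (20.0, 1.0)))
        assert list(s.intervals(25.0)) == [
            (0.0, 10.0, 0.0), (10.0, 20.0, 0.5), (20.0, 25.0, 1.0)
        ]
        assert list(s.intervals(15.0)) == [(0.0, 10.0, 0.0), (10.0, 15.0, 0.5)]

    @pytest.mark.parametrize(
        "segments",
        [(), ((1.0, 0.5),), ((0.0, 0.1), (0.0, 0.2)), ((0.0, -1.0),)],
    )
    def test_invalid_protocols(self, segments):
        with pytest.raises(ValueError):
            SaltProtocol(tuple(segments))


class TestModelState:
    def test_array_roundtrip(self):
        s = ModelState(1.0, 2.0, 3.0)
        assert ModelState.from_array(s.as_array()) == s

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ModelState(float("inf"), 0.0, 0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            ModelState.from_array([1.0, 2.0])
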