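"""Rate-law unit tests: mass action, product-inhibited invertase, effluxes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sucrokin import (
    DomainError,
    EffluxLaw,
    FluxParameters,
    InputError,
    InvertaseParameters,
    MassActionSpec,
    efflux_rate,
    invertase_rate,
    mass_action_rate,
)

conc = st.floats(0.0, 1e3, allow_nan=False)
pos = st.floats(1e-3, 1e3, allow_nan=False)


class TestMassAction:
    @pytest.mark.parametrize(
        "spec, state, expected",
        [
            # zero substrate concentration gives zero forward rate
            (MassActionSpec(1.0, 0.0, (("s", 1),)), {"s": 0.0}, 0.0),
            # hand evaluation: 2 * 3^2
            (MassActionSpec(2.0, 0.0, (("s", 2),)), {"s": 3.0}, 18.0),
            # forward and backward balance at equal concentrations
            (
                MassActionSpec(1.0, 1.0, (("s", 1),), (("p", 1),)),
                {"s": 5.0, "p": 5.0},
                0.0,
            ),
        ],
    )
    def test_examples(self, spec, state, expected):
        assert mass_action_rate(spec, state) == pytest.approx(expected, abs=1e-15)

    def test_missing_species_is_input_error(self):
        spec = MassActionSpec(1.0, 0.0, (("s", 1),))
        with pytest.raises(InputError):
            mass_action_rate(spec, {"other": 1.0})

    def test_negative_concentration_is_domain_error(self):
        spec = MassActionSpec(1.0, 0.0, (("s", 1),))
        with pytest.raises(DomainError):
            mass_action_rate(spec, {"s": -1.0})

    def test_molecularity_below_one_rejected(self):
        with pytest.raises(DomainError):
            MassActionSpec(1.0, 0.0, (("s", 0),))

    @given(k=pos, c=conc, scale=pos)
    @settings(deadline=None, max_examples=50)
    def test_irreversible_monomolecular_rate_is_linear(self, k, c, scale):
        spec = MassActionSpec(k, 0.0, (("s", 1),))
        r1 = mass_action_rate(spec, {"s": c})
        r2 = mass_action_rate(spec, {"s": scale * c})
        assert r2 == pytest.approx(scale * r1, rel=1e-12, abs=1e-12)


class TestInvertaseRate:
    def test_zero_substrate_gives_zero(self, invertase):
        assert invertase_rate(invertase, 0.0, 3.0, 7.0) == 0.0

    def test_half_saturation_identity(self, invertase):
        r = invertase_rate(invertase, invertase.k_m, 0.0, 0.0)
        assert r == pytest.approx(invertase.v_max / 2)

    def test_hand_evaluated_inhibited_point(self):
        # v_max=1, k_m=2, suc=2, glc=k_i_glc halves the uninhibited rate 0.5
        p = InvertaseParameters(v_max=1.0, k_m=2.0, k_i_glc=3.0, k_i_frc=4.0)
        assert invertase_rate(p, 2.0, 3.0, 0.0) == pytest.approx(0.25)

    def test_negative_concentration_rejected(self, invertase):
        with pytest.raises(DomainError):
            invertase_rate(invertase, -1.0, 0.0, 0.0)

    def test_bounded_by_v_max_on_random_states(self, rng):
        for _ in range(20):
            p = InvertaseParameters(
                v_max=rng.uniform(0.5, 20),
                k_m=rng.uniform(0.5, 10),
                k_i_glc=rng.uniform(0.2, 30),
                k_i_frc=rng.uniform(0.2, 30),
            )
            s, g, f = np.exp(rng.uniform(np.log(1e-3), np.log(1e3), size=(3, 500)))
            r = invertase_rate(p, s, g, f)
            assert np.all(r >= 0)
            assert np.all(r <= p.v_max)

    def test_partial_monotonicity(self, invertase, rng):
        s, g, f = np.exp(rng.uniform(np.log(1e-2), np.log(1e2), size=(3, 1000)))
        base = invertase_rate(invertase, s, g, f)
        assert np.all(invertase_rate(invertase, s * 1.1, g, f) >= base)
        assert np.all(invertase_rate(invertase, s, g * 1.1, f) <= base)
        assert np.all(invertase_rate(invertase, s, g, f * 1.1) <= base)

    def test_large_inhibition_constants_recover_michaelis_menten(self, rng):
        p = InvertaseParameters(v_max=3.0, k_m=2.5, k_i_glc=1e9, k_i_frc=1e9)
        s, g, f = np.exp(rng.uniform(np.log(1e-2), np.log(1e2), size=(3, 200)))
        r = invertase_rate(p, s, g, f)
        plain = p.v_max * s / (p.k_m + s)
        assert np.max(np.abs(r - plain) / plain) < 1e-6

    def test_parameter_validation(self):
        with pytest.raises(DomainError):
            InvertaseParameters(v_max=1.0, k_m=0.0, k_i_glc=1.0, k_i_frc=1.0)


class TestEfflux:
    def test_zero_concentration_gives_zero_for_all_kinds(self):
        laws = [
            EffluxLaw.zero(),
            EffluxLaw.first_order(0.3),
            EffluxLaw.michaelis_menten(2.0, 1.5),
        ]
        for law in laws:
            assert law.rate(0.0) == 0.0

    def test_first_order_hand_value(self):
        p = FluxParameters(r_in=0.0, efflux_glc=EffluxLaw.first_order(0.1))
        assert efflux_rate(p, "glc", 10.0) == pytest.approx(1.0)

    def test_michaelis_menten_half_saturation(self):
        law = EffluxLaw.michaelis_menten(v_max=4.0, k_m=3.0)
        assert law.rate(3.0) == pytest.approx(2.0)

    def test_unknown_hexose_rejected(self, fluxes):
        from sucrokin import ConfigError

        with pytest.raises(ConfigError):
            efflux_rate(fluxes, "suc", 1.0)

    def test_derivatives_match_difference_quotient(self):
        law = EffluxLaw.michaelis_menten(v_max=4.0, k_m=3.0)
        c, h = 2.0, 1e-6
        num1 = (law.rate(c + h) - law.rate(c - h)) / (2 * h)
        num2 = (law.rate(c + h) - 2 * law.rate(c) + law.rate(c - h)) / h**2
        assert law.derivative(c) == pytest.approx(num1, rel=1e-8)
        assert law.second_derivative(c) == pytest.approx(num2, rel=1e-3)
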