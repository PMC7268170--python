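"""Regulatory function library: frozen values, bounds, monotonicity, errors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nitroforage import ExperimentSpec, LayerFlags, ModelParameters, ModelState
from nitroforage.model import (
    carbon_fractions,
    cep_production,
    ck_production,
    f_basic_fn,
    f_cep_fn,
    f_local_fn,
    f_systfor_fn,
    f_systrepr_fn,
    g_ck_fn,
    g_ne_fn,
    growth_rate,
    uptake_rate,
)

P = ModelParameters()
CEP_ON = LayerFlags.preset("L3")
CEP_CK_ON = LayerFlags.full()

conc = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


@pytest.mark.parametrize(
    "fn, x, expected",
    [
        # survival response: floor a_basic, midpoint at K_basic
        (lambda v: f_basic_fn(v, P), 0.0, 0.5),
        (lambda v: f_basic_fn(v, P), 0.04, 0.75),
        (lambda v: f_basic_fn(v, P), 0.4, 0.5 + 0.5 * 0.16 / 0.1616),
        # local stimulation: baseline 0.65 without nitrate
        (lambda v: f_local_fn(v, P), 0.0, 0.65),
        (lambda v: f_local_fn(v, P), 200.0, 0.825),
        (lambda v: f_local_fn(v, P), 5000.0, 0.65 + 0.35 * 25e6 / 25.04e6),
        # local-nitrate gate on demand signaling
        (lambda v: g_ne_fn(v, P), 750.0, 0.5),
        (lambda v: g_ne_fn(v, P), 0.0, 0.0),
        (lambda v: g_ne_fn(v, P), 25.0, 625.0 / 563125.0),
        # CK supply gate
        (lambda v: g_ck_fn(v, P), 0.0, 0.1),
        (lambda v: g_ck_fn(v, P), 2.0, 0.55),
        (lambda v: g_ck_fn(v, P), 1e9, 1.0),
        # systemic repression (4th-order, decreasing)
        (lambda v: f_systrepr_fn(v, P), 0.0, 1.0),
        (lambda v: f_systrepr_fn(v, P), 0.4, 0.5),
        (lambda v: f_systrepr_fn(v, P), 0.8, 1.0 / 17.0),
        # systemic foraging boost (decreasing from 1+a_systfor)
        (lambda v: f_systfor_fn(v, P), 0.0, 2.0),
        (lambda v: f_systfor_fn(v, P), 0.12, 1.5),
        (lambda v: f_systfor_fn(v, P), 1e6, 1.0),
    ],
)
def test_regulatory_function_values(fn, x, expected):
    assert fn(x) == pytest.approx(expected, rel=1e-9, abs=1e-9)


@pytest.mark.parametrize(
    "cep_conc, ne, ck_conc, flags, expected",
    [
        (0.0, 1000.0, 5.0, CEP_CK_ON, 1.0),        # no demand signal
        (1e9, 1e9, 0.0, CEP_ON, 1.5),              # saturated, no CK gate
        (1.0, 750.0, 2.0, CEP_CK_ON, 1.06875),     # all half-saturation terms
    ],
)
def test_cep_promotion_values(cep_conc, ne, ck_conc, flags, expected):
    assert f_cep_fn(cep_conc, ne, ck_conc, P, flags) == pytest.approx(expected)


def test_cep_promotion_requires_cep_layer():
    with pytest.raises(ValueError, match="cep layer"):
        f_cep_fn(1.0, 100.0, 1.0, P, LayerFlags.preset("L2"))


@pytest.mark.parametrize(
    "fn",
    [
        lambda v: f_basic_fn(v, P),
        lambda v: f_local_fn(v, P),
        lambda v: g_ne_fn(v, P),
        lambda v: g_ck_fn(v, P),
        lambda v: f_systrepr_fn(v, P),
        lambda v: f_systfor_fn(v, P),
        lambda v: uptake_rate(v, 1.0, P),
        lambda v: cep_production(v, 1.0, P),
        lambda v: ck_production(v, 1.0, P),
    ],
)
def test_negative_input_rejected(fn):
    with pytest.raises(ValueError):
        fn(-1.0)


@given(x=conc)
def test_factor_bounds(x):
    assert P.a_basic <= f_basic_fn(x, P) < 1.0 + 1e-12
    assert 1.0 - P.a_local <= f_local_fn(x, P) < 1.0 + 1e-12
    assert 0.0 <= g_ne_fn(x, P) < 1.0
    assert P.a_CK <= g_ck_fn(x, P) < 1.0 + 1e-12
    assert 0.0 < f_systrepr_fn(x, P) <= 1.0
    assert 1.0 <= f_systfor_fn(x, P) <= 1.0 + P.a_systfor
    assert 1.0 <= f_cep_fn(x, x, x, P, CEP_CK_ON) <= 1.0 + P.a_CEP


@given(a=conc, b=conc)
def test_factor_monotonicity(a, b):
    lo, hi = sorted((a, b))
    assert f_basic_fn(lo, P) <= f_basic_fn(hi, P)
    assert f_local_fn(lo, P) <= f_local_fn(hi, P)
    assert g_ne_fn(lo, P) <= g_ne_fn(hi, P)
    assert g_ck_fn(lo, P) <= g_ck_fn(hi, P)
    assert f_systrepr_fn(lo, P) >= f_systrepr_fn(hi, P)
    assert f_systfor_fn(lo, P) >= f_systfor_fn(hi, P)


@pytest.mark.parametrize(
    "ne, length, expected",
    [
        (0.0, 5.0, 0.0),
        (75.0, 1.0, 0.30045),
        (5000.0, 20.0, 20.0 * (3000.0 / 5075.0 + 0.03)),
    ],
)
def test_uptake_rate_values(ne, length, expected):
    assert uptake_rate(ne, length, P) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "fn, ne, expected",
    [
        (cep_production, 0.0, 0.1),
        (cep_production, 250.0, 0.05),
        (cep_production, 5000.0, 0.1 * 62500.0 / (62500.0 + 25e6)),
        (ck_production, 0.0, 0.0),
        (ck_production, 750.0, 0.05),
        (ck_production, 25.0, 0.1 * 625.0 / 563125.0),
    ],
)
def test_signal_production_values(fn, ne, expected):
    assert fn(ne, 1.0, P) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "r, L, on, expected",
    [
        ((1.0, 1.0), (20.0, 20.0), True, (0.5, 0.5)),
        ((1.0, 0.0), (20.0, 20.0), True, (1.0, 0.0)),
        ((2.0, 1.0), (10.0, 10.0), True, (2.0 / 3.0, 1.0 / 3.0)),
        ((0.0, 0.0), (20.0, 20.0), True, (0.5, 0.5)),   # degenerate: uniform
        ((2.0, 1.0), (10.0, 10.0), False, (0.5, 0.5)),  # layer off: 1/n
    ],
)
def test_carbon_fraction_values(r, L, on, expected):
    np.testing.assert_allclose(
        carbon_fractions(np.array(r), np.array(L), on), expected, rtol=1e-12
    )


@given(
    r=st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=1, max_size=6),
    scale=st.floats(min_value=0.1, max_value=100.0),
)
def test_carbon_fractions_sum_to_one(r, scale):
    n = len(r)
    L = np.full(n, scale)
    g = carbon_fractions(np.array(r), L, True)
    assert g.sum() == pytest.approx(1.0, abs=1e-12)
    if len(set(r)) == 1:  # equal r·L ⇒ uniform allocation
        np.testing.assert_allclose(g, 1.0 / n, atol=1e-12)


def _state(ns: float, n: int = 1) -> ModelState:
    s = ModelState.zero_pools([1.0] * n)
    s.Ns = ns * n  # total length is n mm, so [Ns] = ns
    return s


def test_growth_rate_composition():
    spec0 = ExperimentSpec(ne=(200.0,), duration=1.0, L0=(1.0,),
                           flags=LayerFlags.none())
    assert growth_rate(0, _state(0.4), spec0, P) == 1.0

    spec1 = ExperimentSpec(ne=(200.0,), duration=1.0, L0=(1.0,),
                           flags=LayerFlags.preset("L1"))
    assert growth_rate(0, _state(0.04), spec1, P) == pytest.approx(0.75)

    spec2 = ExperimentSpec(ne=(200.0,), duration=1.0, L0=(1.0,),
                           flags=LayerFlags.preset("L2"))
    expected = (0.5 + 0.5 * 0.16 / 0.1616) * 0.825
    assert growth_rate(0, _state(0.4), spec2, P) == pytest.approx(expected)

    with pytest.raises(IndexError):
        growth_rate(1, _state(0.4), spec2, P)


def test_layerflags_ladder_is_nested_and_validated():
    active = [set(LayerFlags.preset(f"L{i}").active()) for i in range(8)]
    for lower, higher in zip(active, active[1:]):
        assert lower < higher
    assert active[0] == set()
    assert active[1] == {"basic"}
    with pytest.raises(ValueError):
        LayerFlags(ck_gating=True, cep=False)
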