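"""Regulatory function library and the right-hand side of the ODE system.

The effective growth-rate factor of a compartment is the product of the
enabled regulatory functions:

    r_x = f_basic([Ns]) · f_local(Ne_x) · f_CEP([CEPs], Ne_x, [CKs])
          · f_systrepr([Ns]) · f_systfor([Ns])

Each function is a (possibly shifted) second- or fourth-order Hill term of a
nitrate or signal concentration.  Growth of each compartment is the allocated
share of a carbon budget proportional to the total root length (a proxy for
shoot area and hence photosynthesis).
"""

from __future__ import annotations

import numpy as np

from .params import ExperimentSpec, LayerFlags, ModelParameters, ModelState

__all__ = [
    "f_basic_fn",
    "f_local_fn",
    "g_ne_fn",
    "g_ck_fn",
    "f_cep_fn",
    "f_systrepr_fn",
    "f_systfor_fn",
    "growth_factors",
    "growth_rate",
    "carbon_fractions",
    "uptake_rate",
    "cep_production",
    "ck_production",
    "rhs",
]


def _check_nonneg(**values) -> None:
    for name, v in values.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be >= 0, got {v}")


def _hill2(x, k):
    x = np.asarray(x, dtype=float)
    return x * x / (x * x + k * k)


def f_basic_fn(Ns_conc, p: ModelParameters):
    """Survival response: saturating growth dependence on systemic nitrate.

    Rises from ``a_basic`` at [Ns]=0 toward 1, half of the nitrate-dependent
    fraction at ``K_basic``.  The nonzero floor reflects growth fuelled by
    stored nitrate, which the model does not track explicitly.
    """
    _check_nonneg(Ns_conc=Ns_conc)
    return p.a_basic + (1.0 - p.a_basic) * _hill2(Ns_conc, p.K_basic)


def f_local_fn(Ne, p: ModelParameters):
    """Local stimulation by external nitrate (NRT1.1-type sensing).

    Ranges from ``1 - a_local`` without external nitrate toward 1; when
    ``p.f_local_const`` is set (nrt1.1 mutant) the response is that constant.
    """
    _check_nonneg(Ne=Ne)
    if p.f_local_const is not None:
        return p.f_local_const * np.ones_like(np.asarray(Ne, dtype=float))
    return p.a_local * _hill2(Ne, p.K_local) + (1.0 - p.a_local)


def g_ne_fn(Ne, p: ModelParameters):
    """Local-nitrate gate on CEP-driven promotion: Hill(2) in Ne, half at
    ``K_CEP_NE``.  Demand signaling only boosts growth where nitrate is
    actually present."""
    _check_nonneg(Ne=Ne)
    return _hill2(Ne, p.K_CEP_NE)


def g_ck_fn(CKs_conc, p: ModelParameters):
    """CK supply gate on CEP signaling: from ``a_CK`` (no systemic CK) toward
    1, half of the CK-dependent fraction at ``K_CEP_CK``."""
    _check_nonneg(CKs_conc=CKs_conc)
    return p.a_CK + (1.0 - p.a_CK) * _hill2(CKs_conc, p.K_CEP_CK)


def f_cep_fn(CEPs_conc, Ne, CKs_conc, p: ModelParameters, flags: LayerFlags):
    """CEP demand signal: growth promotion up to ``1 + a_CEP``.

    The promotion is gated by local external nitrate (``g_ne_fn``) and, when
    the ``ck_gating`` layer is active, additionally by systemic CK
    (``g_ck_fn``).  Callers must not evaluate this with the cep layer off.
    """
    if not flags.cep:
        raise ValueError("f_cep_fn called with the cep layer disabled")
    _check_nonneg(CEPs_conc=CEPs_conc, Ne=Ne, CKs_conc=CKs_conc)
    boost = p.a_CEP * _hill2(CEPs_conc, p.K_NRT21_CEP) * g_ne_fn(Ne, p)
    if flags.ck_gating:
        boost = boost * g_ck_fn(CKs_conc, p)
    return 1.0 + boost


def f_systrepr_fn(Ns_conc, p: ModelParameters):
    """Systemic repression at high systemic nitrate: decreasing fourth-order
    Hill, half-maximal at ``K_systrepr``."""
    _check_nonneg(Ns_conc=Ns_conc)
    x4 = np.asarray(Ns_conc, dtype=float) ** 4
    k4 = p.K_systrepr ** 4
    return k4 / (k4 + x4)


def f_systfor_fn(Ns_conc, p: ModelParameters):
    """Systemic foraging boost at moderately low systemic nitrate: decreases
    from ``1 + a_systfor`` to 1, half of the boost at ``K_systfor``."""
    _check_nonneg(Ns_conc=Ns_conc)
    x4 = np.asarray(Ns_conc, dtype=float) ** 4
    k4 = p.K_systfor ** 4
    return 1.0 + p.a_systfor * k4 / (x4 + k4)


def growth_factors(
    Ne: np.ndarray,
    Ns_conc: float,
    CEPs_conc: float,
    CKs_conc: float,
    p: ModelParameters,
    flags: LayerFlags,
) -> np.ndarray:
    """Vector of effective growth-rate factors r_x; disabled layers contribute 1."""
    Ne = np.asarray(Ne, dtype=float)
    r = np.ones_like(Ne)
    if flags.basic:
        r = r * f_basic_fn(Ns_conc, p)
    if flags.local:
        r = r * f_local_fn(Ne, p)
    if flags.cep:
        r = r * f_cep_fn(CEPs_conc, Ne, CKs_conc, p, flags)
    if flags.systrepr:
        r = r * f_systrepr_fn(Ns_conc, p)
    if flags.systfor:
        r = r * f_systfor_fn(Ns_conc, p)
    return r


def growth_rate(x: int, state: ModelState, spec: ExperimentSpec,
                p: ModelParameters) -> float:
    """Effective growth-rate factor r_x for compartment ``x``."""
    if not 0 <= x < spec.n:
        raise IndexError(f"compartment index {x} out of range for n={spec.n}")
    r = growth_factors(spec.ne_array, state.Ns_conc, state.CEPs_conc,
                       state.CKs_conc, p, spec.flags)
    return float(r[x])


def carbon_fractions(r: np.ndarray, L: np.ndarray, carbon_flag: bool) -> np.ndarray:
    """Carbon allocation fractions g_x.

    With the carbon layer off every compartment receives the equal share 1/n.
    With it on, allocation follows sink strength: g_x = r_x·L_x / Σ_y r_y·L_y
    (growth rates weighted by compartment size).  If no compartment can grow
    (Σ r·L = 0) the fractions fall back to the uniform 1/n; no growth occurs
    in that case anyway.
    """
    L = np.asarray(L, dtype=float)
    r = np.asarray(r, dtype=float)
    _check_nonneg(r=r)
    if np.any(L <= 0):
        raise ValueError("compartment lengths must be > 0")
    n = L.size
    if not carbon_flag:
        return np.full(n, 1.0 / n)
    w = r * L
    total = w.sum()
    if total <= 0.0:
        return np.full(n, 1.0 / n)
    return w / total


def uptake_rate(Ne, L, p: ModelParameters):
    """Nitrate uptake flux (μmol/h): saturating high-affinity component plus a
    non-saturating low-affinity component, per unit root length."""
    _check_nonneg(Ne=Ne, L=L)
    Ne = np.asarray(Ne, dtype=float)
    return (p.up1 * Ne / (Ne + p.K_up) + p.up2 * Ne) * L


def cep_production(Ne, L, p: ModelParameters):
    """CEP production flux (μmol/h): maximal at zero nitrate, decreasing
    Hill(2) with half-inhibition at ``K_CEP``, per unit root length."""
    _check_nonneg(Ne=Ne, L=L)
    Ne = np.asarray(Ne, dtype=float)
    k2 = p.K_CEP ** 2
    return p.p_CEP * k2 / (k2 + Ne * Ne) * L


def ck_production(Ne, L, p: ModelParameters):
    """CK production flux (μmol/h): increasing Hill(2) in external nitrate,
    half-maximal at ``K_CK``, per unit root length."""
    _check_nonneg(Ne=Ne, L=L)
    return p.p_CK * _hill2(Ne, p.K_CK) * L


def rhs(state: ModelState, spec: ExperimentSpec, p: ModelParameters) -> ModelState:
    """Time derivative of the full state.

    Growth: dL_x/dt = g_x · conv · r_x · ΣL (the published allocation form;
    with the carbon layer off g_x = 1/n).  Nitrate: local pools gain by
    uptake and drain to the systemic pool at rate ``T_up``; the systemic pool
    loses a zeroth-order maintenance flux ``u_m·ΣL`` and a first-order
    exudation flux.  Because the maintenance sink is zeroth-order it is capped
    at the incoming flux whenever Ns ≤ 0 so the pool cannot be driven
    negative.  CEP/CK pools evolve only when their layers are active.
    """
    y = state.pack()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite entry in model state")
    dy = _rhs_packed(y, spec, p)
    return ModelState.unpack(dy, spec.n)


def _rhs_packed(y: np.ndarray, spec: ExperimentSpec, p: ModelParameters) -> np.ndarray:
    """Packed-vector RHS used by both `rhs` and the integrator."""
    n = spec.n
    flags = spec.flags
    Ne = spec.ne_array
    L = y[:n]
    Ni = y[n:2 * n]
    CEP = y[2 * n:3 * n]
    CK = y[3 * n:4 * n]
    Ns, CEPs, CKs = y[4 * n], y[4 * n + 1], y[4 * n + 2]

    sL = L.sum()
    Ns_c = max(Ns, 0.0) / sL
    CEPs_c = max(CEPs, 0.0) / sL
    CKs_c = max(CKs, 0.0) / sL

    r = growth_factors(Ne, Ns_c, CEPs_c, CKs_c, p, flags)
    g = carbon_fractions(r, L, flags.carbon)
    if spec.allocation_mode == "literal":
        dL = g * p.conv * r * sL
    else:  # replace_1_over_n: g allocates the sink-weighted total growth
        dL = g * p.conv * float((r * L).sum())

    dNi = uptake_rate(Ne, L, p) - p.T_up * Ni
    influx = p.T_up * Ni.sum()
    maintenance = p.u_m * sL
    if Ns <= 0.0:
        maintenance = min(maintenance, influx)
    dNs = influx - maintenance - p.e * Ns

    if flags.cep:
        dCEP = cep_production(Ne, L, p) - p.T_CEP * CEP
        dCEPs = p.T_CEP * CEP.sum() - p.d_CEP * CEPs
    else:
        dCEP = np.zeros(n)
        dCEPs = 0.0
    if flags.ck_gating:
        dCK = ck_production(Ne, L, p) - p.T_CK * CK
        dCKs = p.T_CK * CK.sum() - p.d_CK * CKs
    else:
        dCK = np.zeros(n)
        dCKs = 0.0

    return np.concatenate([dL, dNi, dCEP, dCK, [dNs, dCEPs, dCKs]])
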