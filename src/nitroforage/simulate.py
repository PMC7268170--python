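"""Time integration, the analytic exponential-growth oracle and pool fixed points."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import model
from .params import ExperimentSpec, LayerFlags, ModelParameters, ModelState, apply_mutant

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "analytic_length",
    "pool_steady_state",
    "initial_state",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(f"{message} (last valid time t={last_valid_time:g} h)")
        self.last_valid_time = last_valid_time


@dataclass
class Trajectory:
    """Hourly-sampled record of a simulation.

    Arrays are indexed ``[time, compartment]`` where applicable.  ``r`` and
    ``g_carbon`` are the effective growth factors and carbon allocation
    fractions re-evaluated at every sample; concentration columns are μmol/mm.
    """

    spec: ExperimentSpec
    times: np.ndarray           # (T,) hours
    L: np.ndarray               # (T, n) mm
    Ni: np.ndarray              # (T, n) μmol
    CEP: np.ndarray             # (T, n)
    CK: np.ndarray              # (T, n)
    Ns: np.ndarray              # (T,)
    CEPs: np.ndarray            # (T,)
    CKs: np.ndarray             # (T,)
    Ni_conc: np.ndarray         # (T, n)
    Ns_conc: np.ndarray         # (T,)
    CEPs_conc: np.ndarray       # (T,)
    CKs_conc: np.ndarray        # (T,)
    r: np.ndarray               # (T, n)
    g_carbon: np.ndarray        # (T, n)

    @property
    def final_state(self) -> ModelState:
        return ModelState(
            L=self.L[-1], Ni=self.Ni[-1], CEP=self.CEP[-1], CK=self.CK[-1],
            Ns=float(self.Ns[-1]), CEPs=float(self.CEPs[-1]), CKs=float(self.CKs[-1]),
        )

    @property
    def final_lengths(self) -> np.ndarray:
        return self.L[-1]

    @property
    def total_length(self) -> np.ndarray:
        return self.L.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (time, compartment)."""
        T, n = self.L.shape
        rows = {
            "time_h": np.repeat(self.times, n),
            "compartment": np.tile(np.arange(n), T),
            "L_mm": self.L.ravel(),
            "Ni_umol": self.Ni.ravel(),
            "Ni_conc": self.Ni_conc.ravel(),
            "r_factor": self.r.ravel(),
            "g_carbon": self.g_carbon.ravel(),
            "Ns_conc": np.repeat(self.Ns_conc, n),
            "CEPs_conc": np.repeat(self.CEPs_conc, n),
            "CKs_conc": np.repeat(self.CKs_conc, n),
        }
        return pd.DataFrame(rows)


def analytic_length(t, L0: float, r: float, conv: float):
    """Closed-form root length under a constant growth factor: L0·exp(conv·r·t).

    This is the analytic solution of the unregulated growth equation and
    serves as the independent oracle for the integrator.
    """
    if np.any(np.asarray(t) < 0) or L0 < 0 or r < 0 or conv < 0:
        raise ValueError("t, L0, r and conv must all be >= 0")
    return L0 * np.exp(conv * r * np.asarray(t, dtype=float))


def pool_steady_state(
    L, Ne, p: ModelParameters, flags: LayerFlags
) -> tuple[np.ndarray, float, np.ndarray, float, np.ndarray, float]:
    """Closed-form pool fixed points at frozen compartment lengths.

    Returns ``(Ni*, Ns*, CEP*, CEPs*, CK*, CKs*)``.  Local pools balance
    production/uptake against export; systemic pools balance import against
    degradation.  ``Ns*`` is clipped at zero: when maintenance consumption
    exceeds the uptake flux the systemic nitrate pool empties.
    Pools of inactive layers are zero.
    """
    L = np.asarray(L, dtype=float)
    Ne = np.asarray(Ne, dtype=float)
    Ni = model.uptake_rate(Ne, L, p) / p.T_up
    Ns = max(0.0, (p.T_up * Ni.sum() - p.u_m * L.sum()) / p.e)
    if flags.cep:
        CEP = model.cep_production(Ne, L, p) / p.T_CEP
        CEPs = p.T_CEP * CEP.sum() / p.d_CEP
    else:
        CEP = np.zeros_like(L)
        CEPs = 0.0
    if flags.ck_gating:
        CK = model.ck_production(Ne, L, p) / p.T_CK
        CKs = p.T_CK * CK.sum() / p.d_CK
    else:
        CK = np.zeros_like(L)
        CKs = 0.0
    return Ni, Ns, CEP, CEPs, CK, CKs


def initial_state(spec: ExperimentSpec, p: ModelParameters) -> ModelState:
    """Initial condition: lengths at L0, pools empty or pre-equilibrated."""
    state = ModelState.zero_pools(spec.L0_array)
    if spec.init_pools == "steady_state":
        Ni, Ns, CEP, CEPs, CK, CKs = pool_steady_state(
            spec.L0_array, spec.ne_array, p, spec.flags
        )
        state = ModelState(L=spec.L0_array.copy(), Ni=Ni, CEP=CEP, CK=CK,
                           Ns=Ns, CEPs=CEPs, CKs=CKs)
    return state


def integrate(
    spec: ExperimentSpec,
    p: ModelParameters | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_interval: float = 1.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over ``[0, spec.duration]`` with hourly sampling.

    The mutant declared in ``spec`` is applied to the parameter set before
    integration.  Raises :class:`IntegrationError` on solver failure or a
    non-finite/negative terminal state.
    """
    if p is None:
        p = ModelParameters()
    p = apply_mutant(p, spec.mutant)
    n = spec.n

    y0 = initial_state(spec, p).pack()
    times = np.arange(0.0, spec.duration, sample_interval)
    times = np.append(times, spec.duration)

    if spec.duration == 0:
        ys = y0[None, :]
        times = np.array([0.0])
    else:
        sol = solve_ivp(
            lambda t, y: model._rhs_packed(y, spec, p),
            (0.0, spec.duration),
            y0,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=times,
            dense_output=False,
        )
        if not sol.success:
            last = float(sol.t[-1]) if sol.t.size else 0.0
            raise IntegrationError(f"ODE solver failed: {sol.message}", last)
        ys = sol.y.T
        if not np.all(np.isfinite(ys)):
            bad = np.argmax(~np.isfinite(ys).all(axis=1))
            raise IntegrationError("non-finite state encountered",
                                   float(times[max(bad - 1, 0)]))
        # amounts may undershoot zero by solver noise; anything worse is a bug
        if ys.min() < -1e-6:
            raise IntegrationError("state went significantly negative",
                                   float(times[-1]))
        ys = np.clip(ys, 0.0, None)

    # derived per-sample quantities
    T = times.size
    L = ys[:, :n]
    sL = L.sum(axis=1)
    Ns = ys[:, 4 * n]
    CEPs = ys[:, 4 * n + 1]
    CKs = ys[:, 4 * n + 2]
    Ns_c = Ns / sL
    CEPs_c = CEPs / sL
    CKs_c = CKs / sL
    r = np.empty((T, n))
    g = np.empty((T, n))
    for i in range(T):
        r[i] = model.growth_factors(spec.ne_array, Ns_c[i], CEPs_c[i], CKs_c[i],
                                    p, spec.flags)
        g[i] = model.carbon_fractions(r[i], L[i], spec.flags.carbon)

    return Trajectory(
        spec=spec, times=times, L=L,
        Ni=ys[:, n:2 * n], CEP=ys[:, 2 * n:3 * n], CK=ys[:, 3 * n:4 * n],
        Ns=Ns, CEPs=CEPs, CKs=CKs,
        Ni_conc=ys[:, n:2 * n] / L, Ns_conc=Ns_c, CEPs_conc=CEPs_c,
        CKs_conc=CKs_c, r=r, g_carbon=g,
    )
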