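"""Model parameters, regulatory-layer flags, state and experiment containers.

The model describes (part of) an Arabidopsis root system as ``n`` compartments,
each with a cumulative root length ``L_x`` (mm) and local pools of internal
nitrate, CEP peptide and cytokinin (all amounts, μmol).  Single systemic pools
collect nitrate, CEP and CK from all compartments.  Concentrations are defined
per unit root length: local ones relative to the compartment length, systemic
ones relative to the total length of the root system.

``ModelParameters`` is the single source of truth for every rate and
half-saturation constant; its defaults are the published parameterization of
the model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "LayerFlags",
    "ModelState",
    "ExperimentSpec",
    "MUTANTS",
    "LADDER_PRESETS",
    "apply_mutant",
]

#: Recognised in-silico mutants.  Mutants are parameter overrides, not code
#: paths: ``nrt1.1`` pins the local nitrate response at a constant 0.6 and
#: reduces high-affinity uptake by 20%; ``cep`` and ``ck`` zero the respective
#: peptide/hormone production rate.
MUTANTS = ("WT", "nrt1.1", "cep", "ck")

_UNIT_FRACTIONS = ("a_local", "a_CEP", "a_CK", "a_basic", "a_CK")


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants and half-saturation constants of the model.

    Defaults are the published values.  Units follow the convention that
    amounts are μmol, lengths mm, times hours and external nitrate μmol/L.

    Attributes
    ----------
    up1 : float
        Maximum uptake rate of the high-affinity nitrate transporters,
        μmol·mm⁻¹·h⁻¹.
    K_up : float
        External nitrate level at which high-affinity uptake is half-maximal,
        μmol·L⁻¹.
    up2 : float
        Non-saturating low-affinity uptake rate, L·mm⁻¹·h⁻¹.
    T_up : float
        Transport rate from local to systemic nitrate pool, h⁻¹.
    u_m : float
        Nitrate loss to tissue maintenance/turnover, μmol·mm⁻¹·h⁻¹.
    e : float
        Nitrate loss to exudation, h⁻¹.
    conv : float
        Conversion factor from shoot area (proportional to total root length)
        to maximum root length increase; dimensionless.
    a_local, K_local : float
        Amplitude of the external-nitrate-dependent fraction of the local
        growth stimulation and its half-saturation level (μmol·L⁻¹).
    p_CEP, K_CEP, T_CEP, d_CEP : float
        CEP production rate (μmol·mm⁻¹·h⁻¹), half-inhibition nitrate level of
        CEP production (μmol·L⁻¹), local→systemic transport rate (h⁻¹) and
        systemic degradation rate (h⁻¹).
    a_CEP, K_NRT21_CEP, K_CEP_NE : float
        Maximum CEP-driven growth-rate increase, systemic CEP concentration of
        half-maximal promotion (μmol·mm⁻¹), and local nitrate level of
        half-maximal promotion (μmol·L⁻¹).
    p_CK, K_CK, T_CK, d_CK : float
        Analogous constants for cytokinin.
    a_CK, K_CEP_CK : float
        CK-independent fraction of CEP signaling and the systemic CK
        concentration at which the CK-dependent fraction is half-maximal
        (μmol·mm⁻¹).
    a_basic, K_basic : float
        Systemic-nitrate-independent fraction of the survival response and its
        half-saturation concentration (μmol·mm⁻¹).
    a_systfor, K_systfor : float
        Amplitude and half-saturation concentration (μmol·mm⁻¹) of the
        systemic foraging response.
    K_systrepr : float
        Systemic nitrate concentration of half-maximal systemic repression,
        μmol·mm⁻¹.
    f_local_const : float or None
        When set, the local growth stimulation is pinned at this constant
        (used to encode the *nrt1.1* mutant); ``None`` for the wild type.
    """

    up1: float = 0.6
    K_up: float = 75.0
    up2: float = 6e-6
    T_up: float = 3.8
    u_m: float = 0.1
    e: float = 1.5
    conv: float = 0.01
    a_local: float = 0.35
    K_local: float = 200.0
    p_CEP: float = 0.1
    K_CEP: float = 250.0
    T_CEP: float = 0.1
    d_CEP: float = 1e-3
    a_CEP: float = 0.5
    K_NRT21_CEP: float = 1.0
    K_CEP_NE: float = 750.0
    p_CK: float = 0.1
    K_CK: float = 750.0
    T_CK: float = 0.1
    d_CK: float = 1e-3
    a_CK: float = 0.1
    K_CEP_CK: float = 2.0
    a_basic: float = 0.5
    K_basic: float = 0.04
    a_systfor: float = 1.0
    K_systfor: float = 0.12
    K_systrepr: float = 0.4
    f_local_const: float | None = None

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        for name in _UNIT_FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"parameter {name} must lie in [0, 1], got {v}")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **overrides)


def apply_mutant(p: ModelParameters, mutant: str) -> ModelParameters:
    """Return the parameter set encoding an in-silico mutant.

    ``nrt1.1``: local response fixed at 0.6 and ``up1`` reduced by 20%
    (NRT1.1 is both sensor and transporter); ``cep``/``ck``: the respective
    production rate set to zero; ``WT``: unchanged.
    """
    if mutant == "WT":
        return p
    if mutant == "nrt1.1":
        return p.replace(f_local_const=0.6, up1=0.8 * p.up1)
    if mutant == "cep":
        return p.replace(p_CEP=0.0)
    if mutant == "ck":
        return p.replace(p_CK=0.0)
    raise ValueError(f"unknown mutant {mutant!r}; expected one of {MUTANTS}")


@dataclass(frozen=True)
class LayerFlags:
    """Which growth-regulatory layers are active.

    The model was built as a ladder of variants, each adding one layer on top
    of all previous ones; ``preset('L0')`` … ``preset('L7')`` reproduce that
    sequence.  ``ck_gating`` modifies the CEP response and therefore requires
    ``cep``.
    """

    basic: bool = False      # survival response on systemic nitrate
    local: bool = False      # local external-nitrate stimulation
    cep: bool = False        # CEP demand signaling promotes growth
    systrepr: bool = False   # systemic repression at high systemic nitrate
    systfor: bool = False    # systemic foraging boost at low systemic nitrate
    carbon: bool = False     # sink-strength carbon allocation
    ck_gating: bool = False  # CK supply signal gates CEP effectiveness

    def __post_init__(self) -> None:
        if self.ck_gating and not self.cep:
            raise ValueError("ck_gating requires the cep layer to be active")

    _LADDER = (
        "basic", "local", "cep", "systrepr", "systfor", "carbon", "ck_gating",
    )

    @classmethod
    def preset(cls, name: str) -> "LayerFlags":
        """Ladder preset ``'L0'`` (no regulation, r = 1) … ``'L7'`` (full)."""
        try:
            level = LADDER_PRESETS.index(name)
        except ValueError:
            raise ValueError(
                f"unknown preset {name!r}; expected one of {LADDER_PRESETS}"
            ) from None
        return cls(**{layer: True for layer in cls._LADDER[:level]})

    @classmethod
    def full(cls) -> "LayerFlags":
        return cls.preset("L7")

    @classmethod
    def none(cls) -> "LayerFlags":
        return cls.preset("L0")

    def active(self) -> tuple[str, ...]:
        return tuple(name for name in self._LADDER if getattr(self, name))


LADDER_PRESETS = ("L0", "L1", "L2", "L3", "L4", "L5", "L6", "L7")


@dataclass
class ModelState:
    """Per-compartment lengths and pools plus the systemic pools.

    Lengths in mm; all pools are amounts in μmol.  Derived concentrations are
    per unit length: local ones divide by the compartment length, systemic
    ones by the total root length.
    """

    L: np.ndarray
    Ni: np.ndarray
    CEP: np.ndarray
    CK: np.ndarray
    Ns: float
    CEPs: float
    CKs: float

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.Ni = np.asarray(self.Ni, dtype=float)
        self.CEP = np.asarray(self.CEP, dtype=float)
        self.CK = np.asarray(self.CK, dtype=float)
        n = self.L.size
        for name in ("Ni", "CEP", "CK"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must have the same length as L")

    @classmethod
    def zero_pools(cls, L0: Sequence[float]) -> "ModelState":
        L0 = np.asarray(L0, dtype=float)
        z = np.zeros_like(L0)
        return cls(L=L0.copy(), Ni=z.copy(), CEP=z.copy(), CK=z.copy(),
                   Ns=0.0, CEPs=0.0, CKs=0.0)

    @property
    def n(self) -> int:
        return self.L.size

    @property
    def total_length(self) -> float:
        return float(self.L.sum())

    # concentrations (μmol/mm); systemic pools are clipped at zero so that a
    # tiny negative numerical excursion never feeds the regulatory functions
    @property
    def Ni_conc(self) -> np.ndarray:
        return self.Ni / self.L

    @property
    def Ns_conc(self) -> float:
        return max(self.Ns, 0.0) / self.total_length

    @property
    def CEPs_conc(self) -> float:
        return max(self.CEPs, 0.0) / self.total_length

    @property
    def CKs_conc(self) -> float:
        return max(self.CKs, 0.0) / self.total_length

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.L, self.Ni, self.CEP, self.CK, [self.Ns, self.CEPs, self.CKs]]
        )

    @classmethod
    def unpack(cls, y: np.ndarray, n: int) -> "ModelState":
        return cls(
            L=y[:n], Ni=y[n:2 * n], CEP=y[2 * n:3 * n], CK=y[3 * n:4 * n],
            Ns=float(y[4 * n]), CEPs=float(y[4 * n + 1]), CKs=float(y[4 * n + 2]),
        )


@dataclass(frozen=True)
class ExperimentSpec:
    """A single simulation setup.

    Parameters
    ----------
    ne : sequence of float
        External nitrate concentration per compartment, μmol/L; its length
        sets the compartment count ``n``.
    duration : float
        Simulated time in hours.
    L0 : sequence of float, optional
        Initial compartment lengths in mm (default 20 mm each).
    mutant : str
        One of ``MUTANTS``.
    flags : LayerFlags
        Active regulatory layers (default: full model).
    init_pools : {"zero", "steady_state"}
        Whether pools start empty at treatment onset or pre-equilibrated at
        the frozen initial lengths.
    allocation_mode : {"literal", "replace_1_over_n"}
        How carbon allocation enters the growth equation; ``literal`` follows
        the published equation in which the compartment growth factor appears
        both inside the allocation fraction and as the multiplicative rate.
    """

    ne: tuple[float, ...]
    duration: float
    L0: tuple[float, ...] | None = None
    mutant: str = "WT"
    flags: LayerFlags = field(default_factory=LayerFlags.full)
    init_pools: str = "zero"
    allocation_mode: str = "literal"

    def __post_init__(self) -> None:
        ne = tuple(float(v) for v in self.ne)
        object.__setattr__(self, "ne", ne)
        if len(ne) < 1:
            raise ValueError("need at least one compartment")
        if any(v < 0 for v in ne):
            raise ValueError("external nitrate concentrations must be >= 0")
        if not self.duration >= 0:
            raise ValueError("duration must be >= 0")
        L0 = self.L0
        if L0 is None:
            L0 = (20.0,) * len(ne)
        L0 = tuple(float(v) for v in L0)
        if len(L0) != len(ne):
            raise ValueError("L0 must have one entry per compartment")
        if any(v <= 0 for v in L0):
            raise ValueError("initial lengths must be > 0")
        object.__setattr__(self, "L0", L0)
        if self.mutant not in MUTANTS:
            raise ValueError(f"unknown mutant {self.mutant!r}")
        if self.init_pools not in ("zero", "steady_state"):
            raise ValueError("init_pools must be 'zero' or 'steady_state'")
        if self.allocation_mode not in ("literal", "replace_1_over_n"):
            raise ValueError(
                "allocation_mode must be 'literal' or 'replace_1_over_n'"
            )

    @property
    def n(self) -> int:
        return len(self.ne)

    @property
    def ne_array(self) -> np.ndarray:
        return np.asarray(self.ne, dtype=float)

    @property
    def L0_array(self) -> np.ndarray:
        return np.asarray(self.L0, dtype=float)
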