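"""Drivers for the in-silico experiments: dose–response, split root, patch, mutants.

Conditions follow the split-root literature conventions: a plant's root system
is divided over two compartments; ``LN/HN`` denotes the low-nitrate half of a
plant whose other half sees high nitrate, etc.  Default levels are 25 μmol/L
(low) and 5000 μmol/L (high), treatment onset at 20 mm per half, read-outs
after 6 simulated days (144 h); the single-root dose–response runs 8 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    LADDER_PRESETS,
    MUTANTS,
    ExperimentSpec,
    LayerFlags,
    ModelParameters,
)
from .simulate import Trajectory, integrate

__all__ = [
    "NE_LOW",
    "NE_HIGH",
    "SPLIT_ROOT_DURATION_H",
    "DOSE_RESPONSE_DURATION_H",
    "SplitRootSummary",
    "run_dose_response",
    "run_split_root",
    "run_patch",
    "run_mutant_table",
    "PatchResult",
]

NE_LOW = 25.0            # μmol/L, "very low" split-root level
NE_HIGH = 5000.0         # μmol/L, "high" split-root level
SPLIT_ROOT_DURATION_H = 144.0   # final size after 6 days
DOSE_RESPONSE_DURATION_H = 192.0  # cumulative length after 8 days
PATCH_DURATION_H = 144.0


@dataclass(frozen=True)
class SplitRootSummary:
    """Final focal-half lengths (mm) for the four split-root conditions.

    ``difference`` is the preferential-foraging read-out: high-nitrate side
    minus low-nitrate side of the heterogeneous plant.
    """

    ln_ln: float
    ln_hn: float
    hn_ln: float
    hn_hn: float
    mutant: str = "WT"

    @property
    def difference(self) -> float:
        return self.hn_ln - self.ln_hn

    def rounded(self) -> dict[str, int]:
        out = {
            "LN/LN": round(self.ln_ln),
            "LN/HN": round(self.ln_hn),
            "HN/LN": round(self.hn_ln),
            "HN/HN": round(self.hn_hn),
        }
        out["difference"] = out["HN/LN"] - out["LN/HN"]
        return out


def run_dose_response(
    ne_grid,
    flags: LayerFlags,
    duration: float = DOSE_RESPONSE_DURATION_H,
    p: ModelParameters | None = None,
    L0: float = 20.0,
    **integrate_kw,
) -> pd.DataFrame:
    """Single-root (n=1) runs over a grid of homogeneous external nitrate.

    Returns one row per level with the final cumulative length and the local
    and systemic nitrate concentrations at the end of the run.
    """
    ne_grid = np.asarray(ne_grid, dtype=float)
    if ne_grid.size == 0:
        raise ValueError("ne_grid must contain at least one nitrate level")
    rows = []
    for ne in ne_grid:
        spec = ExperimentSpec(ne=(float(ne),), duration=duration,
                              L0=(L0,), flags=flags)
        traj = integrate(spec, p, **integrate_kw)
        rows.append({
            "Ne": float(ne),
            "final_L_mm": float(traj.final_lengths.sum()),
            "Ni_conc": float(traj.Ni_conc[-1, 0]),
            "Ns_conc": float(traj.Ns_conc[-1]),
        })
    return pd.DataFrame(rows)


def run_split_root(
    flags: LayerFlags,
    mutant: str = "WT",
    duration: float = SPLIT_ROOT_DURATION_H,
    ne_low: float = NE_LOW,
    ne_high: float = NE_HIGH,
    L0: float = 20.0,
    p: ModelParameters | None = None,
    init_pools: str = "zero",
    **integrate_kw,
) -> SplitRootSummary:
    """Two-compartment split-root experiment under the three nitrate layouts.

    The homogeneous runs (low/low, high/high) provide the LN/LN and HN/HN
    focal halves; the single heterogeneous run provides both LN/HN (its low
    compartment) and HN/LN (its high compartment), matching how split-root
    data are read.
    """
    def final(ne_pair):
        spec = ExperimentSpec(ne=ne_pair, duration=duration, L0=(L0, L0),
                              mutant=mutant, flags=flags, init_pools=init_pools)
        return integrate(spec, p, **integrate_kw).final_lengths

    low_low = final((ne_low, ne_low))
    het = final((ne_low, ne_high))
    high_high = final((ne_high, ne_high))
    return SplitRootSummary(
        ln_ln=float(low_low[0]),
        ln_hn=float(het[0]),
        hn_ln=float(het[1]),
        hn_hn=float(high_high[0]),
        mutant=mutant,
    )


@dataclass(frozen=True)
class PatchResult:
    """High-patch and summed low-compartment length time series."""

    trajectory: Trajectory
    high_index: int

    @property
    def times(self) -> np.ndarray:
        return self.trajectory.times

    @property
    def L_high(self) -> np.ndarray:
        return self.trajectory.L[:, self.high_index]

    @property
    def L_low_sum(self) -> np.ndarray:
        mask = np.ones(self.trajectory.L.shape[1], dtype=bool)
        mask[self.high_index] = False
        return self.trajectory.L[:, mask].sum(axis=1)


def run_patch(
    n: int = 16,
    high_index: int = 0,
    ck_gating: bool = True,
    duration: float = PATCH_DURATION_H,
    ne_low: float = NE_LOW,
    ne_high: float = NE_HIGH,
    L0: float = 20.0,
    p: ModelParameters | None = None,
    **integrate_kw,
) -> PatchResult:
    """Patchy-soil experiment: one of ``n`` compartments sees high nitrate.

    All compartments start at the same length, so the summed low-nitrate
    length is initially ``(n-1)``-fold the patch length.  Comparing
    ``ck_gating`` on/off shows how the supply signal tempers preferential
    growth in the single high-nitrate patch when demand far outstrips supply.
    """
    if not 0 <= high_index < n:
        raise IndexError(f"high_index {high_index} out of range for n={n}")
    ne = np.full(n, ne_low)
    ne[high_index] = ne_high
    flags = LayerFlags.preset("L7" if ck_gating else "L6")
    spec = ExperimentSpec(ne=tuple(ne), duration=duration, L0=(L0,) * n,
                          flags=flags)
    return PatchResult(trajectory=integrate(spec, p, **integrate_kw),
                       high_index=high_index)


def run_mutant_table(
    duration: float = SPLIT_ROOT_DURATION_H,
    p: ModelParameters | None = None,
    flags: LayerFlags | None = None,
    **split_kw,
) -> pd.DataFrame:
    """Full-model split-root summary for WT and the three mutants.

    Returns the table of low-side length, high-side length and their
    difference (mm, rounded to integers) for WT, nrt1.1, cep and ck plants.
    """
    if flags is None:
        flags = LayerFlags.full()
    rows = []
    for mutant in MUTANTS:
        s = run_split_root(flags, mutant=mutant, duration=duration, p=p,
                           **split_kw)
        rows.append({
            "plant": mutant,
            "length_low_N_mm": round(s.ln_hn),
            "length_high_N_mm": round(s.hn_ln),
            "difference_mm": round(s.hn_ln) - round(s.ln_hn),
        })
    return pd.DataFrame(rows)
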