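"""NADH:NADPH output surfaces over redox-ratio grids.

Inside the cell a G6PDH isozyme sees both cofactor pools at once, and the
split of its flux between NADH and NADPH production depends on the
NAD+/NADH and NADP+/NADPH ratios and on the G6P level.  This module sweeps
:func:`g6pdhkit.kinetics.output_ratio` over a grid of redox ratios at fixed
total pool sizes, converting each ratio r into oxidized = pool.r/(1+r) and
reduced = pool/(1+r).

Default pool totals are 2,600 uM NAD(H) and 400 uM NADP(H) — round numbers
bracketing the ~276 uM intracellular NADPH reported for glucose-grown
P. putida KT2440 — and the default G6P levels are 100 and 1,000 uM, spanning
the physiological order of magnitude.  Pool totals are configurable and are
recorded in every surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, UsageError
from .kinetics import AssayMix, EnzymeKinetics, RateMode, output_ratio

__all__ = ["GridSpec", "OutputSurface", "simulate_grid", "g6p_sensitivity",
           "compare_enzymes", "default_grid"]

FLAG_OK = "ok"
FLAG_INFINITE = "infinite"
FLAG_UNDEFINED = "undefined"


@dataclass(frozen=True)
class GridSpec:
    """Axes and conditions of one output-ratio sweep."""

    nad_ratio_axis: tuple  # NAD+/NADH ratios
    nadp_ratio_axis: tuple  # NADP+/NADPH ratios
    g6p_levels: tuple  # uM
    nad_pool_total: float = 2600.0  # uM NAD+ + NADH
    nadp_pool_total: float = 400.0  # uM NADP+ + NADPH
    e0: float = 1.0  # uM
    mode: RateMode = RateMode.INDEPENDENT

    def __post_init__(self):
        object.__setattr__(self, "nad_ratio_axis", tuple(float(x) for x in self.nad_ratio_axis))
        object.__setattr__(self, "nadp_ratio_axis", tuple(float(x) for x in self.nadp_ratio_axis))
        object.__setattr__(self, "g6p_levels", tuple(float(x) for x in self.g6p_levels))
        object.__setattr__(self, "mode", RateMode(self.mode))
        for name in ("nad_ratio_axis", "nadp_ratio_axis", "g6p_levels"):
            axis = getattr(self, name)
            if len(axis) == 0:
                raise InputError(f"{name} must be non-empty")
            if any(x <= 0 or not math.isfinite(x) for x in axis):
                raise InputError(f"{name} entries must be positive and finite")
        if self.nad_pool_total <= 0 or self.nadp_pool_total <= 0:
            raise InputError("pool totals must be positive")
        if self.e0 <= 0:
            raise InputError("e0 must be positive")

    def mix_at(self, nad_ratio: float, nadp_ratio: float, g6p: float) -> AssayMix:
        """Concentrations implied by one grid cell."""
        return AssayMix(
            g6p=g6p,
            nad_ox=self.nad_pool_total * nad_ratio / (1.0 + nad_ratio),
            nadh=self.nad_pool_total / (1.0 + nad_ratio),
            nadp_ox=self.nadp_pool_total * nadp_ratio / (1.0 + nadp_ratio),
            nadph=self.nadp_pool_total / (1.0 + nadp_ratio),
            e0=self.e0,
        )


def default_grid(mode: RateMode | str = RateMode.INDEPENDENT, n_ratios: int = 25) -> GridSpec:
    """25 log-spaced ratios from 0.01 to 100 on each redox axis, G6P at
    100 uM and 1 mM."""
    axis = tuple(np.logspace(-2, 2, n_ratios))
    return GridSpec(nad_ratio_axis=axis, nadp_ratio_axis=axis,
                    g6p_levels=(100.0, 1000.0), mode=RateMode(mode))


@dataclass
class OutputSurface:
    """NADH:NADPH ratio values over a grid, with per-cell flags."""

    grid: GridSpec
    ratio_values: np.ndarray  # shape (n_nad, n_nadp, n_g6p)
    flags: np.ndarray  # same shape, strings from FLAG_*

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: nad_ratio, nadp_ratio, g6p, ratio, flag."""
        rows = []
        g = self.grid
        for i, rn in enumerate(g.nad_ratio_axis):
            for j, rp in enumerate(g.nadp_ratio_axis):
                for k, g6p in enumerate(g.g6p_levels):
                    rows.append((rn, rp, g6p, self.ratio_values[i, j, k],
                                 self.flags[i, j, k]))
        return pd.DataFrame(rows, columns=["nad_ratio", "nadp_ratio", "g6p",
                                           "ratio", "flag"])

    def finite_values(self) -> np.ndarray:
        return self.ratio_values[self.flags == FLAG_OK]


def simulate_grid(enzyme: EnzymeKinetics, grid: GridSpec) -> OutputSurface:
    """Evaluate the NADH:NADPH output ratio at every grid cell.

    Per-cell kinetics failures become flags; the sweep never aborts.
    """
    shape = (len(grid.nad_ratio_axis), len(grid.nadp_ratio_axis), len(grid.g6p_levels))
    values = np.full(shape, np.nan)
    flags = np.full(shape, FLAG_OK, dtype=object)
    for i, rn in enumerate(grid.nad_ratio_axis):
        for j, rp in enumerate(grid.nadp_ratio_axis):
            for k, g6p in enumerate(grid.g6p_levels):
                try:
                    r = output_ratio(enzyme, grid.mix_at(rn, rp, g6p), grid.mode)
                except Exception:
                    r = math.nan
                values[i, j, k] = r
                if math.isinf(r):
                    flags[i, j, k] = FLAG_INFINITE
                elif math.isnan(r):
                    flags[i, j, k] = FLAG_UNDEFINED
    return OutputSurface(grid=grid, ratio_values=values, flags=flags)


def g6p_sensitivity(enzyme: EnzymeKinetics, grid: GridSpec,
                    surface: OutputSurface | None = None) -> float:
    """Mean absolute log-ratio change between the lowest and highest G6P level.

    Zero iff the surface is G6P-invariant (as it is analytically in
    shared-pool mode).  Cells undefined or infinite at either level are
    excluded.
    """
    if len(grid.g6p_levels) < 2:
        raise UsageError("g6p_sensitivity needs at least two G6P levels")
    if surface is None:
        surface = simulate_grid(enzyme, grid)
    lo = int(np.argmin(grid.g6p_levels))
    hi = int(np.argmax(grid.g6p_levels))
    ok = (surface.flags[:, :, lo] == FLAG_OK) & (surface.flags[:, :, hi] == FLAG_OK)
    if not ok.any():
        raise InputError("all grid cells undefined; cannot compute sensitivity")
    dlog = np.abs(np.log(surface.ratio_values[:, :, hi][ok])
                  - np.log(surface.ratio_values[:, :, lo][ok]))
    return float(dlog.mean())


def compare_enzymes(enzymes: list[EnzymeKinetics], grid: GridSpec) -> pd.DataFrame:
    """Per-enzyme median output ratio and G6P sensitivity on a common grid.

    Rows follow the input order; ties in naming are preserved as given.
    """
    if len(enzymes) == 0:
        raise UsageError("compare_enzymes needs at least one enzyme")
    rows = []
    for enz in enzymes:
        surface = simulate_grid(enz, grid)
        finite = surface.finite_values()
        median = float(np.median(finite)) if finite.size else math.nan
        if len(grid.g6p_levels) >= 2:
            sens = g6p_sensitivity(enz, grid, surface)
        else:
            sens = math.nan
        rows.append({"enzyme": enz.name, "median_ratio": median,
                     "g6p_sensitivity": sens,
                     "n_finite": int(finite.size),
                     "nad_pool_total": grid.nad_pool_total,
                     "nadp_pool_total": grid.nadp_pool_total,
                     "mode": grid.mode.value})
    return pd.DataFrame(rows)
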