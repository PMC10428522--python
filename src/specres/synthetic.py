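"""Synthetic Beer-Lambert spectra for the triclabendazole / levamisole overlap.

The generator emulates the geometry that makes the binary mixture resolvable:
a levamisole-like component (LVM) with a single short-wavelength band peaking
near 214 nm and no measurable absorbance above ~280 nm, and a
triclabendazole-like component (TCB) with two bands — a stronger one at
220 nm, overlapped by LVM, and a second at 304 nm that gives TCB an
"extended" region (290-306 nm) where it absorbs alone.  Band heights per unit
concentration are the published calibration slopes at the respective maxima
(0.1322 and 0.0533 AU/(ug/mL) for TCB at 220/304 nm, 0.0834 for LVM at
214 nm), so synthetic amplitude reads sit on the same scale as the real
instrument responses.

All output is strictly linear in concentration with zero baseline by default;
the exactness oracle for every resolution route rests on this additivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, default_grid

__all__ = [
    "GaussianBand",
    "ComponentModel",
    "NoiseModel",
    "component_spectrum",
    "default_models",
    "mixture_spectrum",
    "table2_grid",
    "DOSAGE_FORM_CONCS",
]

#: Working concentrations (TCB, LVM) in ug/mL produced by the dosage-form
#: dilution chain — the 4:2.5 label ratio diluted into the linear ranges.
DOSAGE_FORM_CONCS = (24.0, 15.0)


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: centre (nm), width sigma (nm), height in AU per
    ug/mL at the centre."""

    center: float
    sigma: float
    height: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("band sigma must be positive")
        if self.height < 0:
            raise ValueError("band height must be non-negative")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return self.height * np.exp(-0.5 * ((grid - self.center) / self.sigma) ** 2)


@dataclass(frozen=True)
class ComponentModel:
    """Gaussian-band Beer-Lambert model of one pure component."""

    name: str
    bands: tuple[GaussianBand, ...]
    baseline: float = 0.0

    def per_unit(self, grid: np.ndarray) -> np.ndarray:
        """Absorbance per 1 ug/mL on ``grid`` (baseline excluded)."""
        out = np.zeros_like(grid, dtype=float)
        for band in self.bands:
            out += band.profile(grid)
        return out


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian photometric noise."""

    sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")

    def sample(self, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.zeros(n)
        return np.random.default_rng(self.seed).normal(0.0, self.sd, n)


def component_spectrum(model: ComponentModel, conc: float,
                       grid: np.ndarray | None = None) -> Spectrum:
    """Pure-component zero-order spectrum at ``conc`` ug/mL."""
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if grid is None:
        grid = default_grid()
    values = conc * model.per_unit(grid) + model.baseline
    return Spectrum(grid, values, order=0, label=f"{model.name} {conc:g} ug/mL")


def default_models() -> tuple[ComponentModel, ComponentModel]:
    """The TCB-like / LVM-like pair.

    Band widths (sigma 8-10 nm) are chosen so the 214 and 220 nm bands
    overlap severely while the 290-306 nm window stays TCB-only: the LVM
    response beyond 285 nm is below 1e-6 AU per ug/mL, far under the division
    guard, so the extended-region assumptions of every route hold by
    construction.
    """
    tcb = ComponentModel("TCB", (
        GaussianBand(220.0, 9.0, 0.1322),
        GaussianBand(304.0, 10.0, 0.0533),
    ))
    lvm = ComponentModel("LVM", (
        GaussianBand(214.0, 8.0, 0.0834),
    ))
    return tcb, lvm


def mixture_spectrum(components: list[tuple[ComponentModel, float]],
                     grid: np.ndarray | None = None,
                     noise: NoiseModel | None = None) -> Spectrum:
    """Binary (or n-ary) mixture spectrum, optionally with seeded noise.

    The label records the true concentrations so downstream recovery studies
    are self-describing.
    """
    if grid is None:
        grid = default_grid()
    values = np.zeros_like(grid, dtype=float)
    parts = []
    for model, conc in components:
        if conc < 0:
            raise ValueError("concentrations must be non-negative")
        values += conc * model.per_unit(grid) + model.baseline
        parts.append(f"{model.name}={conc:g}")
    if noise is not None:
        values = values + noise.sample(grid.size)
    return Spectrum(grid, values, order=0, label="mix " + ",".join(parts))


def table2_grid() -> list[tuple[float, float]]:
    """The specificity study grid of (TCB, LVM) concentrations in ug/mL.

    The five TCB:LVM ratios 2:3, 3:4, 1:1, 4.5:2.5 and 4:2.5 (the dosage-form
    ratio), scaled by 2 ug/mL so every level sits inside the calibration
    ranges (TCB 2-20, LVM 2-14 ug/mL).
    """
    return [(4.0, 6.0), (6.0, 8.0), (10.0, 10.0), (9.0, 5.0), (8.0, 5.0)]
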