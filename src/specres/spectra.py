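"""Spectral containers and the low-level algebra behind ratio-spectra methods.

A :class:`Spectrum` is a sampled absorbance curve on a strictly increasing,
uniform wavelength grid, tagged with a derivative order (0 for the plain
absorption spectrum, 1 for its first derivative with respect to wavelength).
Every resolution technique in :mod:`specres.methods` is a composition of the
pointwise operators defined here: weighted combination, division with a
near-zero guard, finite-difference derivatisation, amplitude reads, plateau
constants and factorisation against a reference wavelength.

Division by a divisor spectrum is only meaningful where the divisor absorbs;
grid points where it falls below the guard ``epsilon`` are *masked* and the
mask travels with the result so that downstream reads and plateau extraction
never consume a singular quotient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "ResponseDescriptor",
    "PlateauConstant",
    "SpectrumError",
    "GridMismatchError",
    "MaskedValueError",
    "ExtrapolationError",
    "FlatnessWarning",
    "default_grid",
    "resample",
    "combine",
    "divide",
    "derivative",
    "read_response",
    "plateau_constant",
    "normalize",
    "factorize",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectra_wide_csv",
    "write_spectra_wide_csv",
]

#: Division guard below which a divisor is treated as non-absorbing (AU).
DEFAULT_EPSILON = 1e-4

#: Relative-standard-deviation threshold above which a plateau is flagged
#: as non-flat (percent).
DEFAULT_FLATNESS_TOL = 2.0

_GRID_ATOL = 1e-9


class SpectrumError(ValueError):
    """Base error for invalid spectral operations."""


class GridMismatchError(SpectrumError):
    """Two spectra do not share a common wavelength grid or order."""


class MaskedValueError(SpectrumError):
    """A read was requested at a wavelength excluded by the division mask."""


class ExtrapolationError(SpectrumError):
    """A resampling target lies outside the source wavelength span."""


class FlatnessWarning(UserWarning):
    """A plateau region is less flat than the stated tolerance."""


def default_grid(start: float = 200.0, stop: float = 400.0, step: float = 0.5) -> np.ndarray:
    """Uniform wavelength grid in nm (default: the 200-400 nm UV scan at 0.5 nm)."""
    n = int(round((stop - start) / step)) + 1
    return np.linspace(start, stop, n)


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing, uniformly spaced wavelengths in nm.
    values
        Response at each wavelength: AU for ``order`` 0, scaled AU/nm for
        ``order`` 1.  Masked points hold NaN.
    order
        Derivative order, 0 or 1.
    label
        Free-text provenance (analyte, concentration, processing chain).
    mask
        Boolean validity per point (``True`` = usable).  ``None`` means all
        points are valid.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    order: int = 0
    label: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size or w.size < 2:
            raise SpectrumError("wavelengths and values must be equal-length 1-D arrays of size >= 2")
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if np.ptp(steps) > _GRID_ATOL:
            raise SpectrumError("wavelength grid must be uniform to within 1e-9 nm")
        if self.order not in (0, 1):
            raise SpectrumError(f"derivative order must be 0 or 1, got {self.order}")
        m = self.mask
        if m is None:
            m = np.ones(w.size, dtype=bool)
        else:
            m = np.asarray(m, dtype=bool)
            if m.shape != w.shape:
                raise SpectrumError("mask must match the grid length")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    # -- basic geometry -------------------------------------------------
    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths.size == other.wavelengths.size
            and np.allclose(self.wavelengths, other.wavelengths, rtol=0, atol=_GRID_ATOL)
        )

    def with_values(self, values: np.ndarray, *, label: str | None = None,
                    order: int | None = None, mask: np.ndarray | None = None) -> "Spectrum":
        return Spectrum(
            self.wavelengths.copy(),
            np.asarray(values, dtype=float),
            order=self.order if order is None else order,
            label=self.label if label is None else label,
            mask=self.mask.copy() if mask is None else mask,
        )

    # -- point reads ----------------------------------------------------
    def value_at(self, lam: float) -> float:
        """Response at ``lam``: the grid value when ``lam`` sits on the grid,
        otherwise linear interpolation between the two bracketing points.

        Raises :class:`MaskedValueError` if any contributing point is masked
        and :class:`ExtrapolationError` outside the span.
        """
        w = self.wavelengths
        if lam < w[0] - _GRID_ATOL or lam > w[-1] + _GRID_ATOL:
            raise ExtrapolationError(
                f"wavelength {lam} nm outside spectrum span [{w[0]}, {w[-1]}] nm")
        pos = (lam - w[0]) / self.step
        i = int(round(pos))
        if abs(pos - i) < 1e-6:  # on-grid
            if not self.mask[i]:
                raise MaskedValueError(f"requested wavelength {lam} nm is masked")
            return float(self.values[i])
        lo = int(np.floor(pos))
        hi = lo + 1
        if not (self.mask[lo] and self.mask[hi]):
            raise MaskedValueError(
                f"interpolation at {lam} nm requires masked neighbours")
        frac = pos - lo
        return float((1 - frac) * self.values[lo] + frac * self.values[hi])


@dataclass(frozen=True)
class ResponseDescriptor:
    """How a scalar analytical response is read off a spectrum.

    ``amplitude_at`` reads the value at ``lambda1``; ``peak_to_peak`` reads
    ``value(lambda1) - value(lambda2)`` (the Pmax-min amplitude of a
    derivative spectrum).
    """

    mode: str  # "amplitude_at" | "peak_to_peak"
    order: int
    lambda1: float
    lambda2: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("amplitude_at", "peak_to_peak"):
            raise SpectrumError(f"unknown response mode {self.mode!r}")
        if self.order not in (0, 1):
            raise SpectrumError("descriptor order must be 0 or 1")
        lams = [self.lambda1] + ([self.lambda2] if self.mode == "peak_to_peak" else [])
        if self.mode == "peak_to_peak":
            if self.lambda2 is None:
                raise SpectrumError("peak_to_peak requires lambda2")
            if self.lambda1 == self.lambda2:
                raise SpectrumError("peak_to_peak requires lambda1 != lambda2")
        for lam in lams:
            if not 200.0 <= float(lam) <= 400.0:
                raise SpectrumError(f"wavelength {lam} nm outside the 200-400 nm scan")

    @property
    def key(self) -> str:
        """Compact label, e.g. ``D0@304`` or ``D1@228-216``."""
        if self.mode == "amplitude_at":
            return f"D{self.order}@{self.lambda1:g}"
        return f"D{self.order}@{self.lambda1:g}-{self.lambda2:g}"

    @classmethod
    def parse(cls, text: str) -> "ResponseDescriptor":
        """Parse ``D0@304`` / ``D1@228-216`` style descriptors."""
        try:
            head, tail = text.strip().split("@")
            order = int(head.upper().lstrip("D"))
            if "-" in tail:
                l1, l2 = (float(x) for x in tail.split("-"))
                return cls("peak_to_peak", order, l1, l2)
            return cls("amplitude_at", order, float(tail))
        except (ValueError, IndexError) as exc:
            raise SpectrumError(f"cannot parse response descriptor {text!r}") from exc


@dataclass(frozen=True)
class PlateauConstant:
    """Mean of a ratio spectrum over a wavelength window, with a flatness
    diagnostic (percent RSD of the ratio across the window)."""

    value: float
    region: tuple[float, float]
    flatness_rsd: float
    flat: bool = True
    n_points: int = 0


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def _require_compatible(a: Spectrum, b: Spectrum) -> None:
    if not a.same_grid(b):
        raise GridMismatchError("spectra are not on a common wavelength grid")
    if a.order != b.order:
        raise GridMismatchError(f"derivative orders differ ({a.order} vs {b.order})")


def resample(spectrum: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new uniform grid inside its span."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    lo, hi = spectrum.span
    if grid[0] < lo - _GRID_ATOL or grid[-1] > hi + _GRID_ATOL:
        raise ExtrapolationError(
            f"target grid [{grid[0]}, {grid[-1]}] nm exceeds source span [{lo}, {hi}] nm")
    values = np.interp(grid, spectrum.wavelengths, spectrum.values)
    if spectrum.mask.all():
        mask = None
    else:
        # a target point is valid only if every source point it draws on is
        mvals = np.interp(grid, spectrum.wavelengths, spectrum.mask.astype(float))
        mask = mvals > 1.0 - 1e-12
        values = np.where(mask, values, np.nan)
    return Spectrum(grid, values, order=spectrum.order, label=spectrum.label, mask=mask)


def combine(a: Spectrum, b: Spectrum, weight_a: float = 1.0, weight_b: float = 1.0) -> Spectrum:
    """Pointwise ``weight_a * a + weight_b * b`` on a common grid and order."""
    _require_compatible(a, b)
    mask = a.mask & b.mask
    values = weight_a * a.values + weight_b * b.values
    values = np.where(mask, values, np.nan)
    return Spectrum(a.wavelengths.copy(), values, order=a.order,
                    label=f"{weight_a:g}*({a.label}) + {weight_b:g}*({b.label})",
                    mask=mask)


def divide(numerator: Spectrum, divisor: Spectrum, epsilon: float = DEFAULT_EPSILON) -> Spectrum:
    """Pointwise ratio spectrum; points where ``|divisor| < epsilon`` are masked."""
    _require_compatible(numerator, divisor)
    if epsilon <= 0:
        raise SpectrumError("epsilon must be positive")
    mask = numerator.mask & divisor.mask & (np.abs(divisor.values) >= epsilon)
    if not mask.any():
        raise SpectrumError("divisor lies entirely below epsilon; ratio undefined everywhere")
    values = np.full_like(numerator.values, np.nan)
    np.divide(numerator.values, divisor.values, out=values, where=mask)
    return Spectrum(numerator.wavelengths.copy(), values, order=numerator.order,
                    label=f"({numerator.label}) / ({divisor.label})", mask=mask)


def derivative(spectrum: Spectrum, delta_lambda: float = 4.0, scale: float = 10.0) -> Spectrum:
    """First derivative over a symmetric window of width ``delta_lambda`` nm,
    multiplied by ``scale``.

    The estimator is the least-squares slope of the spectrum over the
    ``2m + 1`` grid points inside the +/- ``delta_lambda / 2`` window (the
    Savitzky-Golay first-derivative filter): exact on straight lines,
    antisymmetric around Gaussian band centres, and it uses the whole stated
    window rather than only its endpoints, which keeps photometric noise
    amplification down.  The half-window is trimmed from each end of the
    grid; the output order is the input order plus one.
    """
    if spectrum.order != 0:
        raise SpectrumError("only first derivatives of zero-order spectra are supported")
    step = spectrum.step
    k = (delta_lambda / 2.0) / step
    ki = int(round(k))
    if ki < 1 or abs(k - ki) > 1e-9:
        raise SpectrumError(
            f"delta_lambda = {delta_lambda} nm is not representable on a {step} nm grid "
            "(half-window must be a whole number of grid steps)")
    offsets = np.arange(-ki, ki + 1, dtype=float)
    weights = scale * offsets / (step * (offsets**2).sum())
    v = spectrum.values
    win_v = np.lib.stride_tricks.sliding_window_view(v, 2 * ki + 1)
    values = win_v @ weights
    win_m = np.lib.stride_tricks.sliding_window_view(spectrum.mask, 2 * ki + 1)
    mask = win_m.all(axis=1)
    values = np.where(mask, values, np.nan)
    grid = spectrum.wavelengths[ki:-ki]
    return Spectrum(grid, values, order=spectrum.order + 1,
                    label=f"d1({spectrum.label})", mask=mask)


def read_response(spectrum: Spectrum, d: ResponseDescriptor) -> float:
    """Read the scalar response a descriptor names off a spectrum."""
    if d.order != spectrum.order:
        raise SpectrumError(
            f"descriptor order {d.order} does not match spectrum order {spectrum.order}")
    if d.mode == "amplitude_at":
        return spectrum.value_at(d.lambda1)
    return spectrum.value_at(d.lambda1) - spectrum.value_at(d.lambda2)


def plateau_constant(ratio: Spectrum, region: tuple[float, float],
                     flatness_tol: float = DEFAULT_FLATNESS_TOL) -> PlateauConstant:
    """Mean of a ratio spectrum over ``region`` (inclusive), restricted to
    unmasked points.

    The flatness RSD (percent) diagnoses whether the window really is a
    plateau; exceeding ``flatness_tol`` attaches a :class:`FlatnessWarning`
    but still returns the constant, since real spectra drift.
    """
    lo, hi = region
    if not hi > lo:
        raise SpectrumError("plateau region must have positive width")
    w = ratio.wavelengths
    sel = (w >= lo - _GRID_ATOL) & (w <= hi + _GRID_ATOL) & ratio.mask & np.isfinite(ratio.values)
    n = int(sel.sum())
    if n < 3:
        raise SpectrumError(
            f"plateau region [{lo}, {hi}] nm holds only {n} unmasked points (need >= 3)")
    vals = ratio.values[sel]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if mean == 0.0:
        rsd = 0.0 if sd == 0.0 else float("inf")
    else:
        rsd = 100.0 * sd / abs(mean)
    flat = rsd <= flatness_tol
    if not flat:
        warnings.warn(
            f"plateau over [{lo}, {hi}] nm has RSD {rsd:.3g}% > {flatness_tol}% tolerance",
            FlatnessWarning, stacklevel=2)
    return PlateauConstant(value=mean, region=(float(lo), float(hi)),
                           flatness_rsd=rsd, flat=flat, n_points=n)


def normalize(spectrum: Spectrum, concentration: float) -> Spectrum:
    """Scale a pure-component spectrum to its per-unit (1 ug/mL) form."""
    if concentration <= 0:
        raise SpectrumError("concentration must be positive")
    return spectrum.with_values(spectrum.values / concentration,
                                label=f"{spectrum.label} (normalized)")


def factorize(spectrum: Spectrum, lambda_ref: float, epsilon: float = DEFAULT_EPSILON) -> Spectrum:
    """Divide a spectrum by its own response at ``lambda_ref`` so the result
    reads exactly 1 there.

    Under Beer-Lambert linearity the factorized spectrum is concentration
    invariant, which is what makes the factorized-response route divisor-free.
    """
    ref = spectrum.value_at(lambda_ref)
    if abs(ref) < epsilon:
        raise SpectrumError(
            f"reference response {ref:.3g} at {lambda_ref} nm is below epsilon = {epsilon}")
    return spectrum.with_values(spectrum.values / ref,
                                label=f"{spectrum.label} (factorized @ {lambda_ref:g} nm)")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def read_spectrum_csv(path, order: int = 0, label: str | None = None) -> Spectrum:
    """Read a two-column spectrum CSV (``wavelength_nm,absorbance``)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectrumError(f"{path}: expected two columns (wavelength_nm, absorbance)")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float),
                    order=order, label=label if label is not None else str(path))


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a two-column spectrum CSV at 9 significant digits."""
    df = pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                       "absorbance": spectrum.values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra_wide_csv(path, order: int = 0) -> dict[str, Spectrum]:
    """Read a wide CSV (first column wavelength, one column per spectrum)."""
    df = pd.read_csv(path)
    w = df.iloc[:, 0].to_numpy(float)
    return {col: Spectrum(w, df[col].to_numpy(float), order=order, label=col)
            for col in df.columns[1:]}


def write_spectra_wide_csv(spectra: dict[str, Spectrum], path) -> None:
    first = next(iter(spectra.values()))
    data = {"wavelength_nm": first.wavelengths}
    for name, s in spectra.items():
        if not s.same_grid(first):
            raise GridMismatchError("wide CSV requires a common grid")
        data[name] = s.values
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
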