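"""Linear calibration and method-validation statistics.

Covers the validation surface of a spectrophotometric assay: ordinary
least-squares calibration with LOD/LOQ, recovery, intra/inter-day precision,
two-sample comparison against a reference method (pooled-variance t and
variance-ratio F at p = 0.05) and single-factor ANOVA.

LOD and LOQ follow the ICH/VICH residual-based convention,
``3.3 * s / |slope|`` and ``10 * s / |slope|``, where ``s`` is the residual
standard deviation of the calibration fit unless a blank SD is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .spectra import ResponseDescriptor

__all__ = [
    "CalibrationCurve",
    "CalibrationSet",
    "Prediction",
    "MethodComparison",
    "AnovaTable",
    "fit_calibration",
    "predict",
    "recovery",
    "precision",
    "compare_methods",
    "anova_single_factor",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS calibration of a response descriptor against concentration."""

    analyte: str
    response: ResponseDescriptor | None
    slope: float
    intercept: float
    r: float
    conc_range: tuple[float, float]
    lod: float
    loq: float
    sd_residuals: float
    n: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not self.conc_range[0] < self.conc_range[1]:
            raise ValueError("concentration range must be increasing")
        if self.lod > self.loq:
            raise ValueError("LOD cannot exceed LOQ")


class Prediction(NamedTuple):
    value: float
    below_lod: bool


def fit_calibration(concs: Sequence[float], responses: Sequence[float],
                    descriptor: ResponseDescriptor | None = None,
                    analyte: str = "",
                    conc_range: tuple[float, float] | None = None,
                    blank_sd: float | None = None) -> CalibrationCurve:
    """Fit response = slope * conc + intercept by OLS.

    ``blank_sd`` overrides the residual SD in the LOD/LOQ formulas when a
    blank-based estimate is preferred.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired calibration points")
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.ptp(x) == 0:
        raise ValueError("concentrations are rank deficient (all equal)")
    if conc_range is None:
        conc_range = (float(x.min()), float(x.max()))
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    dof = x.size - 2
    sd = blank_sd if blank_sd is not None else float(np.sqrt((resid ** 2).sum() / dof))
    lod = 3.3 * sd / abs(fit.slope)
    loq = 10.0 * sd / abs(fit.slope)
    return CalibrationCurve(
        analyte=analyte, response=descriptor,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), conc_range=conc_range,
        lod=lod, loq=loq, sd_residuals=float(sd), n=int(x.size),
    )


def predict(curve: CalibrationCurve, response: float) -> Prediction:
    """Invert the calibration; the flag marks results below the LOD
    (reported, never clipped)."""
    value = (response - curve.intercept) / curve.slope
    return Prediction(value=float(value), below_lod=bool(value < curve.lod))


def recovery(found: float, taken: float) -> float:
    """Percent recovery, 100 * found / taken."""
    if taken <= 0:
        raise ValueError("taken concentration must be positive")
    return 100.0 * found / taken


def precision(replicates_by_day: Mapping[object, Sequence[float]]) -> tuple[float, float]:
    """(intra-day RSD %, inter-day RSD %) from day-grouped replicates.

    Intra-day pools the within-day sample variances; inter-day is the RSD of
    the full replicate set across days.  Both are relative to the grand mean.
    """
    groups = [np.asarray(v, dtype=float) for v in replicates_by_day.values()]
    if len(groups) < 1 or any(g.size < 2 for g in groups):
        raise ValueError("each day needs >= 2 replicates")
    allv = np.concatenate(groups)
    grand = allv.mean()
    if grand == 0:
        raise ValueError("grand mean is zero; RSD undefined")
    num = sum((g.size - 1) * g.var(ddof=1) for g in groups)
    den = sum(g.size - 1 for g in groups)
    sd_intra = np.sqrt(num / den)
    sd_inter = allv.std(ddof=1)
    return 100.0 * float(sd_intra) / abs(grand), 100.0 * float(sd_inter) / abs(grand)


@dataclass(frozen=True)
class MethodComparison:
    """Pooled-variance t and variance-ratio F against a reference method."""

    t: float
    t_crit: float
    t_dof: int
    f: float
    f_crit: float
    f_dof: tuple[int, int]
    alpha: float
    t_significant: bool
    f_significant: bool


def compare_methods(a: Sequence[float], b: Sequence[float],
                    alpha: float = 0.05) -> MethodComparison:
    """Two-sample comparison: pooled-variance Student's t (two-sided) and the
    larger/smaller variance-ratio F, each against its critical value."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per method")
    t_res = stats.ttest_ind(x, y, equal_var=True)
    t_dof = x.size + y.size - 2
    t_crit = float(stats.t.ppf(1 - alpha / 2, t_dof))
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx >= vy:
        f_val, f_dof = vx / vy if vy > 0 else np.inf, (x.size - 1, y.size - 1)
    else:
        f_val, f_dof = vy / vx if vx > 0 else np.inf, (y.size - 1, x.size - 1)
    if vx == vy:
        f_val = 1.0
    f_crit = float(stats.f.ppf(1 - alpha, *f_dof))
    t_abs = float(abs(t_res.statistic))
    return MethodComparison(
        t=float(t_res.statistic), t_crit=t_crit, t_dof=t_dof,
        f=float(f_val), f_crit=f_crit, f_dof=f_dof, alpha=alpha,
        t_significant=t_abs > t_crit, f_significant=float(f_val) > f_crit,
    )


@dataclass(frozen=True)
class AnovaTable:
    """Single-factor ANOVA with the SS partition identity."""

    ss_between: float
    df_between: int
    ms_between: float
    ss_within: float
    df_within: int
    ms_within: float
    ss_total: float
    df_total: int
    f: float
    f_crit: float
    p: float


def anova_single_factor(groups: Sequence[Sequence[float]],
                        alpha: float = 0.05) -> AnovaTable:
    """One-way ANOVA across k groups (SS_total = SS_between + SS_within)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    allv = np.concatenate(gs)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    ss_total = ((allv - grand) ** 2).sum()
    df_between = len(gs) - 1
    df_within = allv.size - len(gs)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within if ms_within > 0 else (0.0 if ms_between == 0 else np.inf)
    f_crit = float(stats.f.ppf(1 - alpha, df_between, df_within))
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaTable(
        ss_between=float(ss_between), df_between=df_between, ms_between=float(ms_between),
        ss_within=float(ss_within), df_within=df_within, ms_within=float(ms_within),
        ss_total=float(ss_total), df_total=allv.size - 1,
        f=float(f), f_crit=f_crit, p=p,
    )


class CalibrationSet:
    """Named lookup of calibration curves, keyed ``analyte:descriptor``
    (e.g. ``TCB:D0@304``, ``TCB:DD1@230-220``, ``TCB:CV``)."""

    def __init__(self, curves: Mapping[str, CalibrationCurve] | None = None):
        self._curves: dict[str, CalibrationCurve] = dict(curves or {})

    def add(self, key: str, curve: CalibrationCurve) -> None:
        self._curves[key] = curve

    def get(self, key: str) -> CalibrationCurve:
        try:
            return self._curves[key]
        except KeyError:
            raise KeyError(
                f"no calibration curve for {key!r}; available: {sorted(self._curves)}"
            ) from None

    def predict(self, key: str, response: float) -> Prediction:
        return predict(self.get(key), response)

    def keys(self):
        return self._curves.keys()

    def items(self):
        return self._curves.items()

    def __contains__(self, key: str) -> bool:
        return key in self._curves

    def __len__(self) -> int:
        return len(self._curves)
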