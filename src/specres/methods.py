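"""The nine spectrophotometric resolution and quantification routes.

All routes exploit the same asymmetry: the extended component (TCB) absorbs
alone in a long-wavelength window (290-306 nm on the plain spectrum,
280-315 nm on its first derivative), while both components overlap severely
below 250 nm.  Dividing the mixture spectrum by a pure divisor of the
extended component yields a ratio spectrum whose plateau over that window
equals the concentration ratio c_analyte / c_divisor — the "plateau
constant" that every constant-based route starts from.

Zero-order routes
    RS-SS   ratio subtraction + spectrum subtraction: subtract the plateau
            constant from the ratio spectrum, multiply back by the divisor
            to resolve the less extended component, then subtract it from
            the mixture to recover the extended one.
    CM-SS   constant multiplication: multiply the constant by the divisor to
            resolve the extended component directly; subtract for the other.
    FC-SS   factorized response: no divisor — multiply the mixture amplitude
            at the interference-free wavelength (304 nm) by the factorized
            pure spectrum (unit response at 304 nm), subtract for the rest.

First-derivative routes (DS-SS, D1CM-SS, D1FC-SS) apply the identical
algebra after derivatising mixture and divisor (window 4 nm, scale 10); the
derivative being linear, the plateau constant is unchanged.

DD1 derivatises the mixture/pure-divisor ratio so the divisor component's
contribution (a constant) vanishes; the remaining amplitude is proportional
to the other component alone.  CV maps the plateau constant against a
normalized divisor through a dedicated regression; CNV reads that same
constant directly as the concentration, since dividing by a per-unit pure
spectrum makes the plateau equal c_analyte exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .calibration import CalibrationSet
from .spectra import (
    DEFAULT_EPSILON,
    DEFAULT_FLATNESS_TOL,
    PlateauConstant,
    ResponseDescriptor,
    Spectrum,
    SpectrumError,
    combine,
    derivative,
    divide,
    factorize,
    normalize,
    plateau_constant,
    read_response,
)
from .synthetic import ComponentModel, component_spectrum

__all__ = [
    "Method",
    "MethodConfig",
    "ResolutionResult",
    "default_config",
    "load_configs",
    "ratio_subtraction_ss",
    "constant_multiplication_ss",
    "factorized_ss",
    "derivative_route",
    "derivative_ratio",
    "constant_value",
    "concentration_value",
    "resolve_mixture",
    "curve_key",
]


class Method(str, enum.Enum):
    RS_SS = "RS_SS"
    CM_SS = "CM_SS"
    FC_SS = "FC_SS"
    DS_SS = "DS_SS"
    D1CM_SS = "D1CM_SS"
    D1FC_SS = "D1FC_SS"
    DD1 = "DD1"
    CV = "CV"
    CNV = "CNV"


#: Routes whose spectral algebra runs on first-derivative spectra.
D1_ROUTES = {Method.DS_SS, Method.D1CM_SS, Method.D1FC_SS}
#: Routes that resolve both component spectra and satisfy the conservation
#: identity resolved_X + resolved_Y = mixture.
SS_ROUTES = {Method.RS_SS, Method.CM_SS, Method.FC_SS,
             Method.DS_SS, Method.D1CM_SS, Method.D1FC_SS}


@dataclass
class MethodConfig:
    """Everything a route needs besides the spectra themselves."""

    method: Method
    extended: str = "TCB"
    less_extended: str = "LVM"
    #: divisor concentration in ug/mL for constant-based routes
    divisor_conc: float | None = None
    #: DD1: target analyte -> (divisor analyte, divisor conc ug/mL)
    dd1_divisors: dict[str, tuple[str, float]] | None = None
    plateau_region: tuple[float, float] | None = None
    factorization_ref: float | None = None
    responses: dict[str, ResponseDescriptor] = field(default_factory=dict)
    alt_responses: dict[str, tuple[ResponseDescriptor, ...]] = field(default_factory=dict)
    epsilon: float = DEFAULT_EPSILON
    flatness_tol: float = DEFAULT_FLATNESS_TOL
    derivative_window: float = 4.0
    derivative_scale: float = 10.0

    def __post_init__(self) -> None:
        m = Method(self.method)
        self.method = m
        if m in {Method.RS_SS, Method.CM_SS, Method.DS_SS, Method.D1CM_SS,
                 Method.CV, Method.CNV} and self.plateau_region is None:
            raise SpectrumError(f"{m.value} requires a plateau region")
        if m in {Method.FC_SS, Method.D1FC_SS} and self.factorization_ref is None:
            raise SpectrumError(f"{m.value} requires a factorization reference wavelength")
        if m is Method.DD1 and not self.dd1_divisors:
            raise SpectrumError("DD1 requires per-analyte divisors")


@dataclass
class ResolutionResult:
    """Outcome of one route on one mixture."""

    method: Method
    resolved_spectra: dict[str, Spectrum] = field(default_factory=dict)
    constants: dict[str, PlateauConstant] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    below_lod: dict[str, bool] = field(default_factory=dict)
    extra_concentrations: dict[str, float] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    def conservation_residual(self, mixture: Spectrum) -> float:
        """Max |resolved_X + resolved_Y - mixture| over unmasked points; the
        identity holds by construction for every SS-coupled route.

        ``mixture`` is order-matched first: a zero-order mixture is
        derivatised before being compared with resolved derivative spectra.
        """
        import numpy as np

        spectra = list(self.resolved_spectra.values())
        if len(spectra) != 2:
            raise SpectrumError("conservation requires exactly two resolved spectra")
        total = combine(spectra[0], spectra[1], 1.0, 1.0)
        if mixture.order == 0 and total.order == 1:
            mixture = derivative(mixture)
        if not total.same_grid(mixture):
            from .spectra import resample
            mixture = resample(mixture, total.wavelengths)
        sel = total.mask & mixture.mask
        return float(np.max(np.abs(total.values[sel] - mixture.values[sel])))


def curve_key(method: Method, analyte: str, desc: ResponseDescriptor | None,
              cv_analyte: str | None = None) -> str:
    """Calibration lookup key for a route/analyte/descriptor triple."""
    method = Method(method)
    if method is Method.DD1:
        tail = desc.key.split("@", 1)[1]
        return f"{analyte}:DD1@{tail}"
    if method in {Method.CV, Method.CNV} and analyte == cv_analyte:
        return f"{analyte}:CV"
    return f"{analyte}:{desc.key}"


# ---------------------------------------------------------------------------
# default / bundled configuration
# ---------------------------------------------------------------------------

def _amp(order: int, lam: float) -> ResponseDescriptor:
    return ResponseDescriptor("amplitude_at", order, lam)


def _pp(order: int, l1: float, l2: float) -> ResponseDescriptor:
    return ResponseDescriptor("peak_to_peak", order, l1, l2)


def default_config(method: Method | str) -> MethodConfig:
    """The shipped TCB/LVM configuration: divisors, plateau windows and
    measurement wavelengths for each route."""
    m = Method(method)
    if m is Method.RS_SS:
        return MethodConfig(m, divisor_conc=5.0, plateau_region=(290.0, 306.0),
                            responses={"TCB": _amp(0, 304), "LVM": _amp(0, 214)},
                            alt_responses={"TCB": (_amp(0, 220),)})
    if m is Method.CM_SS:
        return MethodConfig(m, divisor_conc=5.0, plateau_region=(290.0, 306.0),
                            responses={"TCB": _amp(0, 220), "LVM": _amp(0, 214)})
    if m is Method.FC_SS:
        return MethodConfig(m, factorization_ref=304.0,
                            responses={"TCB": _amp(0, 220), "LVM": _amp(0, 214)})
    if m is Method.DS_SS:
        return MethodConfig(m, divisor_conc=5.0, plateau_region=(280.0, 315.0),
                            responses={"TCB": _amp(1, 310), "LVM": _amp(1, 221)},
                            alt_responses={"TCB": (_pp(1, 228, 216),)})
    if m is Method.D1CM_SS:
        return MethodConfig(m, divisor_conc=5.0, plateau_region=(280.0, 315.0),
                            responses={"TCB": _pp(1, 228, 216), "LVM": _amp(1, 221)})
    if m is Method.D1FC_SS:
        return MethodConfig(m, factorization_ref=310.0,
                            responses={"TCB": _pp(1, 228, 216), "LVM": _amp(1, 221)})
    if m is Method.DD1:
        return MethodConfig(m,
                            dd1_divisors={"TCB": ("LVM", 4.0), "LVM": ("TCB", 3.0)},
                            responses={"TCB": _pp(1, 230, 220), "LVM": _amp(1, 219)})
    if m is Method.CV:
        return MethodConfig(m, plateau_region=(290.0, 306.0),
                            responses={"LVM": _amp(0, 214)})
    if m is Method.CNV:
        return MethodConfig(m, plateau_region=(290.0, 306.0),
                            responses={"LVM": _amp(0, 214)})
    raise SpectrumError(f"unknown method {method!r}")


def load_configs(path=None) -> dict[Method, MethodConfig]:
    """Load per-method configs from YAML (the bundled ``tcb_lvm.yaml`` when
    no path is given)."""
    if path is None:
        text = resources.files("specres").joinpath("data/tcb_lvm.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    extended = doc.get("analytes", {}).get("extended", "TCB")
    less = doc.get("analytes", {}).get("less_extended", "LVM")
    out: dict[Method, MethodConfig] = {}
    for name, spec in doc["methods"].items():
        m = Method(name)
        responses = {a: ResponseDescriptor.parse(d)
                     for a, d in (spec.get("responses") or {}).items()}
        alt = {a: tuple(ResponseDescriptor.parse(d) for d in ds)
               for a, ds in (spec.get("alt_responses") or {}).items()}
        dd1 = None
        if spec.get("dd1_divisors"):
            dd1 = {a: (v["analyte"], float(v["conc"]))
                   for a, v in spec["dd1_divisors"].items()}
        region = tuple(spec["plateau_region"]) if spec.get("plateau_region") else None
        out[m] = MethodConfig(
            m, extended=extended, less_extended=less,
            divisor_conc=spec.get("divisor_conc"),
            dd1_divisors=dd1, plateau_region=region,
            factorization_ref=spec.get("factorization_ref"),
            responses=responses, alt_responses=alt,
        )
    return out


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

def _read_concentrations(result: ResolutionResult, cfg: MethodConfig,
                         calib: CalibrationSet) -> None:
    for analyte, desc in cfg.responses.items():
        spec = result.resolved_spectra[analyte]
        resp = read_response(spec, desc)
        pred = calib.predict(curve_key(cfg.method, analyte, desc), resp)
        result.concentrations[analyte] = pred.value
        result.below_lod[analyte] = pred.below_lod
        if pred.below_lod:
            result.diagnostics.append(f"{analyte}: result below LOD")
    for analyte, descs in cfg.alt_responses.items():
        spec = result.resolved_spectra[analyte]
        for desc in descs:
            resp = read_response(spec, desc)
            pred = calib.predict(curve_key(cfg.method, analyte, desc), resp)
            result.extra_concentrations[f"{analyte}:{desc.key}"] = pred.value


def _constant_and_note(mixture: Spectrum, divisor: Spectrum,
                       cfg: MethodConfig, result: ResolutionResult) -> PlateauConstant:
    ratio = divide(mixture, divisor, epsilon=cfg.epsilon)
    k = plateau_constant(ratio, cfg.plateau_region, flatness_tol=cfg.flatness_tol)
    result.constants["plateau"] = k
    if not k.flat:
        result.diagnostics.append(
            f"plateau RSD {k.flatness_rsd:.3g}% exceeds {cfg.flatness_tol}% tolerance")
    n_masked = int((~ratio.mask).sum())
    if n_masked:
        result.diagnostics.append(f"ratio spectrum: {n_masked} masked points")
    return k


# ---------------------------------------------------------------------------
# the routes
# ---------------------------------------------------------------------------

def ratio_subtraction_ss(mixture: Spectrum, divisor: Spectrum,
                         cfg: MethodConfig, calib: CalibrationSet) -> ResolutionResult:
    """RS-SS: (mixture / divisor - k) * divisor resolves the less extended
    component; subtracting it from the mixture resolves the extended one.

    The multiply-back product equals ``mixture - k * divisor`` wherever the
    ratio is defined, and that closed form extends it to divisor-masked
    points, so the resolved spectra carry no mask holes.
    """
    result = ResolutionResult(cfg.method)
    k = _constant_and_note(mixture, divisor, cfg, result)
    resolved_less = combine(mixture, divisor, 1.0, -k.value)
    resolved_less = resolved_less.with_values(
        resolved_less.values, label=f"resolved {cfg.less_extended} ({cfg.method.value})")
    resolved_more = combine(mixture, resolved_less, 1.0, -1.0)
    resolved_more = resolved_more.with_values(
        resolved_more.values, label=f"resolved {cfg.extended} ({cfg.method.value})")
    result.resolved_spectra = {cfg.less_extended: resolved_less,
                               cfg.extended: resolved_more}
    _read_concentrations(result, cfg, calib)
    return result


def constant_multiplication_ss(mixture: Spectrum, divisor: Spectrum,
                               cfg: MethodConfig, calib: CalibrationSet) -> ResolutionResult:
    """CM-SS: k * divisor resolves the extended component directly; spectrum
    subtraction recovers the other."""
    result = ResolutionResult(cfg.method)
    k = _constant_and_note(mixture, divisor, cfg, result)
    resolved_more = divisor.with_values(
        k.value * divisor.values,
        label=f"resolved {cfg.extended} ({cfg.method.value})")
    resolved_less = combine(mixture, resolved_more, 1.0, -1.0)
    resolved_less = resolved_less.with_values(
        resolved_less.values, label=f"resolved {cfg.less_extended} ({cfg.method.value})")
    result.resolved_spectra = {cfg.extended: resolved_more,
                               cfg.less_extended: resolved_less}
    _read_concentrations(result, cfg, calib)
    return result


def factorized_ss(mixture: Spectrum, factorized: Spectrum,
                  cfg: MethodConfig, calib: CalibrationSet,
                  interferent: Spectrum | None = None,
                  leakage_tol: float = 1e-3) -> ResolutionResult:
    """FC-SS: amplitude at the interference-free wavelength times the
    factorized pure spectrum resolves the extended component without any
    divisor; spectrum subtraction recovers the other.

    If a pure interferent spectrum is supplied, its response at the
    factorization wavelength is checked against the zero-contribution
    assumption and a diagnostic is attached when it leaks.
    """
    ref = cfg.factorization_ref
    result = ResolutionResult(cfg.method)
    unit = factorized.value_at(ref)
    if abs(unit - 1.0) > 1e-9:
        raise SpectrumError(
            f"factorized spectrum reads {unit:.6g} (not 1) at {ref} nm")
    if interferent is not None:
        leak = interferent.value_at(ref)
        if abs(leak) > leakage_tol:
            result.diagnostics.append(
                f"interferent responds {leak:.3g} AU at {ref} nm; "
                "zero-contribution assumption violated")
    amp = read_response(mixture, ResponseDescriptor("amplitude_at", mixture.order, ref))
    resolved_more = factorized.with_values(
        amp * factorized.values, label=f"resolved {cfg.extended} ({cfg.method.value})")
    resolved_less = combine(mixture, resolved_more, 1.0, -1.0)
    resolved_less = resolved_less.with_values(
        resolved_less.values, label=f"resolved {cfg.less_extended} ({cfg.method.value})")
    result.resolved_spectra = {cfg.extended: resolved_more,
                               cfg.less_extended: resolved_less}
    _read_concentrations(result, cfg, calib)
    return result


def derivative_route(mixture: Spectrum, divisor_source: Spectrum,
                     cfg: MethodConfig, calib: CalibrationSet,
                     route: Method | str | None = None) -> ResolutionResult:
    """DS-SS / D1CM-SS / D1FC-SS: derivatise mixture and divisor, then apply
    the corresponding zero-order algebra verbatim on the order-1 spectra.

    ``divisor_source`` is the zero-order pure extended-component spectrum:
    the stated-concentration divisor for DS/D1CM, any concentration for
    D1FC (factorisation cancels it).
    """
    route = Method(route) if route is not None else cfg.method
    if route not in D1_ROUTES:
        raise SpectrumError(f"{route} is not a first-derivative route")
    if mixture.order != 0 or divisor_source.order != 0:
        raise SpectrumError("derivative routes start from zero-order spectra")
    d1_mix = derivative(mixture, cfg.derivative_window, cfg.derivative_scale)
    d1_div = derivative(divisor_source, cfg.derivative_window, cfg.derivative_scale)
    if route is Method.DS_SS:
        return ratio_subtraction_ss(d1_mix, d1_div, cfg, calib)
    if route is Method.D1CM_SS:
        return constant_multiplication_ss(d1_mix, d1_div, cfg, calib)
    factorized = factorize(d1_div, cfg.factorization_ref, epsilon=cfg.epsilon)
    return factorized_ss(d1_mix, factorized, cfg, calib)


def derivative_ratio(mixture: Spectrum, divisor: Spectrum, cfg: MethodConfig,
                     calib: CalibrationSet, analyte: str) -> ResolutionResult:
    """DD1 for one analyte: first derivative of mixture / pure-divisor; the
    divisor component's own contribution (a constant in the ratio) vanishes
    on derivatisation, leaving an amplitude proportional to ``analyte``."""
    result = ResolutionResult(Method.DD1)
    ratio = divide(mixture, divisor, epsilon=cfg.epsilon)
    dr = derivative(ratio, cfg.derivative_window, cfg.derivative_scale)
    desc = cfg.responses[analyte]
    resp = read_response(dr, desc)
    pred = calib.predict(curve_key(Method.DD1, analyte, desc), resp)
    result.resolved_spectra[analyte] = dr
    result.concentrations[analyte] = pred.value
    result.below_lod[analyte] = pred.below_lod
    return result


def _ss_complement(mixture: Spectrum, normalized_divisor: Spectrum,
                   conc_extended: float, cfg: MethodConfig,
                   calib: CalibrationSet, result: ResolutionResult) -> None:
    # spectrum-subtraction complement: rebuild the extended component from
    # its found concentration, subtract, read the other analyte
    key = curve_key(Method.RS_SS, cfg.less_extended, cfg.responses[cfg.less_extended])
    if key not in calib:
        return
    resolved_more = normalized_divisor.with_values(
        conc_extended * normalized_divisor.values,
        label=f"resolved {cfg.extended} ({cfg.method.value})")
    resolved_less = combine(mixture, resolved_more, 1.0, -1.0)
    desc = cfg.responses[cfg.less_extended]
    pred = calib.predict(key, read_response(resolved_less, desc))
    result.resolved_spectra[cfg.extended] = resolved_more
    result.resolved_spectra[cfg.less_extended] = resolved_less.with_values(
        resolved_less.values, label=f"resolved {cfg.less_extended} ({cfg.method.value})")
    result.concentrations[cfg.less_extended] = pred.value
    result.below_lod[cfg.less_extended] = pred.below_lod
    result.diagnostics.append(
        f"{cfg.less_extended} obtained by spectrum-subtraction complement")


def constant_value(mixture: Spectrum, normalized_divisor: Spectrum,
                   cfg: MethodConfig, calib: CalibrationSet) -> ResolutionResult:
    """CV: the plateau constant of mixture / normalized divisor, substituted
    in the constant-vs-concentration regression (slope ~ 1 on ideal data)."""
    result = ResolutionResult(Method.CV)
    k = _constant_and_note(mixture, normalized_divisor, cfg, result)
    pred = calib.predict(f"{cfg.extended}:CV", k.value)
    result.concentrations[cfg.extended] = pred.value
    result.below_lod[cfg.extended] = pred.below_lod
    _ss_complement(mixture, normalized_divisor, pred.value, cfg, calib, result)
    return result


def concentration_value(mixture: Spectrum, normalized_divisor: Spectrum,
                        cfg: MethodConfig, calib: CalibrationSet | None = None) -> ResolutionResult:
    """CNV: dividing by the per-unit pure spectrum makes the plateau constant
    the concentration itself — no regression step."""
    result = ResolutionResult(Method.CNV)
    k = _constant_and_note(mixture, normalized_divisor, cfg, result)
    result.concentrations[cfg.extended] = k.value
    result.below_lod[cfg.extended] = False
    if calib is not None:
        _ss_complement(mixture, normalized_divisor, k.value, cfg, calib, result)
    return result


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def resolve_mixture(mixture: Spectrum, method: Method | str,
                    calib: CalibrationSet,
                    models: dict[str, ComponentModel],
                    cfg: MethodConfig | None = None) -> ResolutionResult:
    """Run one route on a zero-order mixture spectrum, constructing the
    divisor / factorized / normalized spectra it needs from pure-component
    models on the mixture's own grid."""
    method = Method(method)
    if cfg is None:
        cfg = default_config(method)
    grid = mixture.wavelengths
    ext_model = models[cfg.extended]

    if method in {Method.RS_SS, Method.CM_SS}:
        divisor = component_spectrum(ext_model, cfg.divisor_conc, grid)
        fn = ratio_subtraction_ss if method is Method.RS_SS else constant_multiplication_ss
        return fn(mixture, divisor, cfg, calib)
    if method is Method.FC_SS:
        pure = component_spectrum(ext_model, 10.0, grid)
        factorized = factorize(pure, cfg.factorization_ref, epsilon=cfg.epsilon)
        interferent = component_spectrum(models[cfg.less_extended], 10.0, grid)
        return factorized_ss(mixture, factorized, cfg, calib, interferent=interferent)
    if method in D1_ROUTES:
        conc = cfg.divisor_conc if cfg.divisor_conc is not None else 10.0
        source = component_spectrum(ext_model, conc, grid)
        return derivative_route(mixture, source, cfg, calib, method)
    if method is Method.DD1:
        merged = ResolutionResult(Method.DD1)
        for analyte, (div_name, div_conc) in cfg.dd1_divisors.items():
            divisor = component_spectrum(models[div_name], div_conc, grid)
            part = derivative_ratio(mixture, divisor, cfg, calib, analyte)
            merged.resolved_spectra.update(part.resolved_spectra)
            merged.concentrations.update(part.concentrations)
            merged.below_lod.update(part.below_lod)
            merged.diagnostics.extend(part.diagnostics)
        return merged
    if method in {Method.CV, Method.CNV}:
        norm = normalize(component_spectrum(ext_model, 10.0, grid), 10.0)
        if method is Method.CV:
            return constant_value(mixture, norm, cfg, calib)
        return concentration_value(mixture, norm, cfg, calib)
    raise SpectrumError(f"unknown method {method!r}")
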