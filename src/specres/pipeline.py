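"""End-to-end study orchestration.

Simulates (or loads) calibration series and mixtures, fits every calibration
curve, runs all nine resolution routes over the specificity ratio grid and a
dosage-form scenario, and emits recovery / calibration / statistics reports
plus greenness output.  Everything is seeded: re-running with the same
configuration and seed reproduces the reports byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import greenness as gm
from .calibration import (
    CalibrationSet,
    anova_single_factor,
    compare_methods,
    fit_calibration,
    recovery,
)
from .methods import Method, MethodConfig, default_config, resolve_mixture
from .spectra import (
    ResponseDescriptor,
    Spectrum,
    default_grid,
    derivative,
    divide,
    normalize,
    plateau_constant,
    read_response,
)
from .synthetic import (
    DOSAGE_FORM_CONCS,
    ComponentModel,
    NoiseModel,
    component_spectrum,
    default_models,
    mixture_spectrum,
    table2_grid,
)

__all__ = [
    "DosageFormSpec",
    "StudyConfig",
    "StudyReport",
    "dilution_chain",
    "build_calibration_set",
    "run_study",
]


@dataclass(frozen=True)
class DosageFormSpec:
    """A labelled two-component suspension and its dilution scheme."""

    label_tcb: float  # mg per mL of suspension
    label_lvm: float
    dilution_steps: tuple[tuple[float, float], ...]  # (aliquot mL, final volume mL)

    def __post_init__(self) -> None:
        if not self.dilution_steps:
            raise ValueError("need at least one dilution step")
        for aliquot, final in self.dilution_steps:
            if aliquot <= 0 or final <= 0:
                raise ValueError("volumes must be positive")
            if aliquot > final:
                raise ValueError("aliquot cannot exceed the final volume")


#: The shipped dosage form: 120 mg TCB + 75 mg LVM per mL, diluted
#: 1 mL -> 100 mL then 1 mL -> 50 mL to reach the working range.
ERADEX_FORTE = DosageFormSpec(120.0, 75.0, ((1.0, 100.0), (1.0, 50.0)))


def dilution_chain(spec: DosageFormSpec) -> dict[str, float]:
    """Working concentrations in ug/mL after the sequential dilutions."""
    out = {}
    for name, label in (("TCB", spec.label_tcb), ("LVM", spec.label_lvm)):
        conc = label * 1000.0  # mg/mL -> ug/mL
        for aliquot, final in spec.dilution_steps:
            conc *= aliquot / final
        out[name] = conc
    return out


# ---------------------------------------------------------------------------
# calibration construction
# ---------------------------------------------------------------------------

#: Calibration levels per descriptor family (ug/mL), spanning the linear
#: ranges: TCB 2-20 at 304 nm, 1-10 at 220 nm, LVM 2-14.
TCB_WIDE = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0)
TCB_NARROW = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
LVM_LEVELS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)


def build_calibration_set(models: dict[str, ComponentModel],
                          grid: np.ndarray | None = None,
                          noise_sd: float = 0.0,
                          seed: int = 0) -> CalibrationSet:
    """Fit every calibration curve the nine routes consume, from simulated
    standard series of the pure components.

    With ``noise_sd`` 0 the slopes equal the models' per-unit responses and
    the intercepts vanish; a positive SD emulates replicate standards read
    on a noisy instrument.
    """
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    tcb, lvm = models["TCB"], models["LVM"]

    def noisy(values: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return values
        return values + rng.normal(0.0, noise_sd, values.shape)

    def pure(model: ComponentModel, conc: float) -> Spectrum:
        s = component_spectrum(model, conc, grid)
        return s.with_values(noisy(s.values))

    calib = CalibrationSet()

    def add(key: str, analyte: str, desc: ResponseDescriptor | None,
            concs, responses) -> None:
        calib.add(key, fit_calibration(concs, responses, descriptor=desc,
                                       analyte=analyte))

    # zero-order amplitude curves
    for analyte, model, lam, concs in (
        ("TCB", tcb, 304.0, TCB_WIDE),
        ("TCB", tcb, 220.0, TCB_NARROW),
        ("LVM", lvm, 214.0, LVM_LEVELS),
    ):
        desc = ResponseDescriptor("amplitude_at", 0, lam)
        resp = [read_response(pure(model, c), desc) for c in concs]
        add(f"{analyte}:{desc.key}", analyte, desc, concs, resp)

    # first-derivative curves
    for analyte, model, desc, concs in (
        ("TCB", tcb, ResponseDescriptor("amplitude_at", 1, 310.0), TCB_WIDE),
        ("TCB", tcb, ResponseDescriptor("peak_to_peak", 1, 228.0, 216.0), TCB_NARROW),
        ("LVM", lvm, ResponseDescriptor("amplitude_at", 1, 221.0), LVM_LEVELS),
    ):
        resp = [read_response(derivative(pure(model, c)), desc) for c in concs]
        add(f"{analyte}:{desc.key}", analyte, desc, concs, resp)

    # DD1 curves: pure analyte over the other component's divisor
    for analyte, model, div_model, div_conc, desc, concs in (
        ("TCB", tcb, lvm, 4.0,
         ResponseDescriptor("peak_to_peak", 1, 230.0, 220.0), TCB_WIDE),
        ("LVM", lvm, tcb, 3.0,
         ResponseDescriptor("amplitude_at", 1, 219.0), LVM_LEVELS),
    ):
        div = component_spectrum(div_model, div_conc, grid)
        resp = [read_response(derivative(divide(pure(model, c), div)), desc)
                for c in concs]
        tail = desc.key.split("@", 1)[1]
        add(f"{analyte}:DD1@{tail}", analyte, desc, concs, resp)

    # CV curve: plateau constant against the normalized divisor vs concentration
    norm = normalize(component_spectrum(tcb, 10.0, grid), 10.0)
    ks = [plateau_constant(divide(pure(tcb, c), norm), (290.0, 306.0)).value
          for c in TCB_WIDE]
    add("TCB:CV", "TCB", None, TCB_WIDE, ks)

    return calib


# ---------------------------------------------------------------------------
# the study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    methods: tuple[Method, ...] = tuple(Method)
    ratios: tuple[tuple[float, float], ...] = tuple(table2_grid())
    include_dosage_form: bool = True
    replicates: int = 3
    noise_sd: float = 0.002
    calibration_noise_sd: float = 0.0
    reference_method: Method = Method.RS_SS


@dataclass
class StudyReport:
    recoveries: pd.DataFrame           # per-method / per-level mean +/- SD
    replicate_recoveries: pd.DataFrame  # raw per-replicate values
    calibration: pd.DataFrame
    comparisons: pd.DataFrame
    anova: dict
    greenness: dict
    log: list[str]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.recoveries.to_csv(out / "recoveries.csv", index=False, float_format="%.6g")
        self.replicate_recoveries.to_csv(out / "replicate_recoveries.csv",
                                         index=False, float_format="%.9g")
        self.calibration.to_csv(out / "calibration.csv", index=False, float_format="%.6g")
        self.comparisons.to_csv(out / "comparisons.csv", index=False, float_format="%.6g")
        with open(out / "report.json", "w") as fh:
            json.dump({"anova": self.anova, "greenness": self.greenness}, fh, indent=2)
        (out / "log.txt").write_text("\n".join(self.log) + "\n")


def _replicate_seed(base_seed: int, mi: int, ri: int, rep: int) -> int:
    ss = np.random.SeedSequence([base_seed, mi, ri, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def run_study(config: StudyConfig | None = None, seed: int = 0,
              outdir=None) -> StudyReport:
    """Run the full specificity study: every configured route over every
    concentration level, with seeded replicate noise."""
    config = config or StudyConfig()
    tcb, lvm = default_models()
    models = {"TCB": tcb, "LVM": lvm}
    grid = default_grid()
    log: list[str] = [f"seed={seed} noise_sd={config.noise_sd} "
                      f"replicates={config.replicates}"]

    calib = build_calibration_set(models, grid,
                                  noise_sd=config.calibration_noise_sd,
                                  seed=_replicate_seed(seed, 999, 0, 0))
    cal_rows = []
    for key, curve in sorted(calib.items()):
        cal_rows.append({"curve": key, "slope": curve.slope,
                         "intercept": curve.intercept, "r": curve.r,
                         "range_low": curve.conc_range[0],
                         "range_high": curve.conc_range[1],
                         "lod": curve.lod, "loq": curve.loq, "n": curve.n})
    calibration_df = pd.DataFrame(cal_rows)

    levels = [(f"{t:g}:{l:g}", t, l) for t, l in config.ratios]
    if config.include_dosage_form:
        t, l = DOSAGE_FORM_CONCS
        levels.append((f"dosage {t:g}:{l:g}", t, l))

    rep_rows = []
    for mi, method in enumerate(config.methods):
        cfg = default_config(method)
        for ri, (label, c_tcb, c_lvm) in enumerate(levels):
            for rep in range(config.replicates):
                noise = None
                if config.noise_sd > 0:
                    noise = NoiseModel(config.noise_sd,
                                       _replicate_seed(seed, mi, ri, rep))
                mix = mixture_spectrum([(tcb, c_tcb), (lvm, c_lvm)], grid, noise)
                try:
                    result = resolve_mixture(mix, method, calib, models, cfg)
                except Exception as exc:  # recorded per cell, not fatal
                    log.append(f"{method.value} {label} rep{rep}: FAILED {exc}")
                    continue
                for key, k in result.constants.items():
                    log.append(f"{method.value} {label} rep{rep}: {key}="
                               f"{k.value:.6g} (RSD {k.flatness_rsd:.3g}%)")
                for note in result.diagnostics:
                    log.append(f"{method.value} {label} rep{rep}: {note}")
                truth = {"TCB": c_tcb, "LVM": c_lvm}
                for analyte, found in result.concentrations.items():
                    rep_rows.append({
                        "method": Method(method).value, "level": label,
                        "analyte": analyte, "replicate": rep,
                        "taken": truth[analyte], "found": found,
                        "recovery_pct": recovery(found, truth[analyte]),
                    })
    replicate_df = pd.DataFrame(rep_rows)

    summary = (replicate_df
               .groupby(["method", "level", "analyte"], sort=False)["recovery_pct"]
               .agg(mean_recovery_pct="mean", sd="std", n="count")
               .reset_index())

    # method-vs-method statistics on the pooled TCB recoveries
    ref = Method(config.reference_method).value
    pooled = {m: g["recovery_pct"].to_numpy()
              for m, g in replicate_df[replicate_df.analyte == "TCB"].groupby("method")}
    comp_rows = []
    for m, vals in pooled.items():
        if m == ref or ref not in pooled or len(vals) < 2 or len(pooled[ref]) < 2:
            continue
        c = compare_methods(pooled[ref], vals)
        comp_rows.append({"method": m, "reference": ref, "t": c.t,
                          "t_crit": c.t_crit, "F": c.f, "f_crit": c.f_crit,
                          "t_significant": c.t_significant,
                          "f_significant": c.f_significant})
    comparisons_df = pd.DataFrame(comp_rows)
    anova_dict = {}
    if len(pooled) >= 2 and all(len(v) >= 2 for v in pooled.values()):
        a = anova_single_factor(list(pooled.values()))
        anova_dict = {"ss_between": a.ss_between, "df_between": a.df_between,
                      "ms_between": a.ms_between, "ss_within": a.ss_within,
                      "df_within": a.df_within, "ms_within": a.ms_within,
                      "ss_total": a.ss_total, "F": a.f, "F_crit": a.f_crit,
                      "p": a.p}

    eco_p, agree_p, nemi_p = gm.load_profile()
    eco = gm.eco_scale(eco_p)
    green = {"eco_scale": {"total_score": eco.total_score, "grade": eco.grade,
                           "penalty_points": eco.per_item_pps},
             "agree": gm.agree_score(agree_p),
             "nemi": gm.nemi(nemi_p)}

    report = StudyReport(recoveries=summary, replicate_recoveries=replicate_df,
                         calibration=calibration_df, comparisons=comparisons_df,
                         anova=anova_dict, greenness=green, log=log)
    if outdir is not None:
        report.write(outdir)
    return report
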