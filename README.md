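# specres

Spectrophotometric resolution of binary mixtures with severely overlapping
UV spectra, built around the triclabendazole (TCB) / levamisole HCl (LVM)
anthelmintic pair.

Quality-control labs often need to assay two co-formulated drugs whose UV
absorption spectra overlap so strongly below 250 nm that neither can be read
directly. When one component is *more extended* — here TCB, whose 304 nm band
persists over 290–306 nm where LVM does not absorb — a family of
ratio-spectra manipulations can mathematically filter each component's
spectrum out of the mixture without any chromatographic separation.
`specres` implements nine such quantification routes, the calibration and
validation statistics used to qualify them, and the green-chemistry scoring
(Eco-Scale, AGREE, NEMI) used to grade the procedure, all exercisable on
synthetic Beer–Lambert spectra so the whole workflow runs without an
instrument.

## The methods

Let `M(λ)` be the mixture spectrum and `Y'(λ)` a pure divisor spectrum of
the extended component at concentration `c_div`. Under Beer–Lambert
linearity the ratio `M/Y'` is flat over the extended region and its plateau
value is the concentration ratio

```
k = mean_{λ ∈ plateau} M(λ)/Y'(λ) = c_Y / c_div .
```

The routes compose this constant with pointwise spectral algebra:

| route | order | idea |
|---|---|---|
| RS-SS  | D⁰ | `(M/Y' − k)·Y'` resolves the less extended X; `M − X` resolves Y |
| CM-SS  | D⁰ | `k·Y'` resolves Y directly; subtraction gives X |
| FC-SS  | D⁰ | amplitude at 304 nm × factorized pure spectrum (unit response at 304 nm); no divisor |
| DS-SS, D¹CM-SS, D¹FC-SS | D¹ | the same algebra after derivatising mixture and divisor (window 4 nm, scale 10); plateau 280–315 nm |
| DD¹    | D¹ of ratio | derivative of `M / X'` cancels the divisor component; the residual amplitude is ∝ the other component |
| CV     | D⁰ | plateau constant against a *normalized* (per 1 µg/mL) divisor, mapped through its own regression |
| CNV    | D⁰ | the same constant read directly as the concentration (slope 1, intercept 0 by construction) |

Resolved spectra are read at the analytes' maxima (TCB 304/220 nm, LVM
214 nm on D⁰; TCB P310 and P228−216, LVM P221 on D¹; P230−220 and P219 on
the derivative-ratio spectra) and converted through ordinary least-squares
calibration curves with ICH/VICH-style LOD/LOQ. Validation statistics cover
recovery, intra/inter-day precision, pooled-variance *t*, variance-ratio
*F* and single-factor ANOVA.

## Worked example

```python
from specres import (Method, NoiseModel, default_grid, default_models,
                     mixture_spectrum, resolve_mixture)
from specres.pipeline import build_calibration_set

tcb, lvm = default_models()                 # Gaussian-band Beer-Lambert models
models = {"TCB": tcb, "LVM": lvm}
grid = default_grid()                       # 200-400 nm at 0.5 nm
calib = build_calibration_set(models, grid)

mix = mixture_spectrum([(tcb, 10.0), (lvm, 10.0)], grid,
                       NoiseModel(sd=0.002, seed=7))
result = resolve_mixture(mix, Method.RS_SS, calib, models)
k = result.constants["plateau"]
print(f"plateau constant = {k.value:.4f}  (RSD {k.flatness_rsd:.2f}% over {k.region})")
for analyte, conc in result.concentrations.items():
    print(f"{analyte}: {conc:.3f} ug/mL  (recovery {100*conc/10:.2f}%)")
```

prints

```
plateau constant = 2.0016  (RSD 0.44% over (290.0, 306.0))
TCB: 10.008 ug/mL  (recovery 100.08%)
LVM: 9.989 ug/mL  (recovery 99.89%)
```

The plateau constant sits at 2.00 because the 10 µg/mL mixture was divided
by a 5 µg/mL TCB divisor; both analytes are recovered to ~0.1% despite
0.002 AU photometric noise. On noiseless input every route recovers both
concentrations to machine precision.

A command-line interface mirrors the workflow:

```sh
specres simulate --conc TCB=10,LVM=10 --noise 0.002 --seed 7 --out mix.csv
specres resolve --method RS_SS --mixture mix.csv --out result.json
specres greenness --out green.json
specres run --seed 7 --out results/       # full study: 9 routes x 6 levels
```

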