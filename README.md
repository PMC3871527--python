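# dcepk

DCE-MRI transvascular-parameter analysis for small-animal test–retest
studies: nested kinetic-model fitting with per-voxel model selection, and
the cohort statistics used to read acute treatment effects off paired
imaging sessions. A synthetic-cohort generator produces fully specified
virtual rat-glioma studies (ground-truth parameter maps, plasma curve,
noisy dual-echo / Look-Locker / DWI series), so every stage of the pipeline
can be validated against known truth.

## The problem

In dynamic contrast-enhanced MRI a gadolinium bolus is tracked through
tissue at high temporal resolution. In brain tumors the blood–brain barrier
leaks, and the leakage parameters are candidate biomarkers of acute
vascular drug effects: an animal is imaged once before and once after
treatment, and the per-animal change in each parameter is compared across
treatment-time cohorts.

Each voxel's concentration time-course `Ct(t)`, driven by the plasma curve
`Cp(t)`, is described by one of three nested models:

* **Model 1** (intact barrier): `Ct = vp·Cp`
* **Model 2** (influx only, Patlak): `Ct = vp·Cp + Ktrans·∫₀ᵗ Cp dτ`
* **Model 3** (influx + backflux, extended Tofts):
  `Ct = vp·Cp + Ktrans·∫₀ᵗ Cp(τ)·e^(−kep(t−τ)) dτ`

with `vp` the fractional plasma volume, `Ktrans` (min⁻¹) the forward volume
transfer constant, `kep` (min⁻¹) the backflux rate and `ve = Ktrans/kep`
the interstitial volume fraction. Because the models are nested least-squares
problems, each voxel is assigned the lowest order that the data support via
sequential F-tests

```
F = ((SSE_a − SSE_b)/(p_b − p_a)) / (SSE_b/(n − p_b)),
```

and only Model-3 voxels — where all three parameters are identifiable —
enter the cohort statistics: per-group paired t-tests, a one-way ANOVA over
treatment times, and a planned contrast pooling the early (2 & 4 h) against
the late (12 & 24 h) groups.

The raw-signal side of the pipeline covers the acquisition physics: a
three-parameter Look-Locker fit with apparent-T1 correction
(`T1 = T1*·(B/A − 1)`), dual-echo splitting (`R2* = ln(S1/S2)/ΔTE`) with
TE→0 extrapolation, exact inversion of the spoiled gradient-echo equation
for `R1(t)`, and `Ct = (R1(t) − R1,pre)/r1`. A two-point ADC map
(`ADC = ln(S_b0/S_b1)/(b1 − b0)`) supports tumor localization.

## Worked example

```python
from dcepk import AcquisitionSpec, make_aif, forward_model, fit_model

spec = AcquisitionSpec()          # 150 frames @ 4 s, bolus at frame 15
aif = make_aif(spec)              # biexponential plasma curve, peak 4.5 mM
ct = forward_model(3, aif, vp=0.02, ktrans=0.02, kep=0.4)
res = fit_model(3, ct, aif)
print(f"vp={res.vp3:.4f}  Ktrans={res.ktrans3:.4f}/min  "
      f"kep={res.kep3:.3f}/min  ve={res.ve3:.4f}")
```

prints

```
vp=0.0200  Ktrans=0.0200/min  kep=0.400/min  ve=0.0500
```

— the generating parameters recovered to numerical precision (the separable
fit profiles the linear pair over a golden-section search in `kep`).

A full virtual study runs from the shell:

```bash
dcepk run --seed 7 --out results/demo
```

which simulates the default 31-animal design (five cohorts treated 2, 4, 8,
12 and 24 h before the retest scan), analyzes every session, and writes
per-animal NIfTI maps plus `cohort_table.csv`, `stats_report.json` and
boxplot-ready CSVs (the run configuration is validated JSON; its schema
ships in `docs/pipeline_config.schema.json`). On the default design the
report shows the signature
temporal pattern: pooled `Ktrans` differences positive for the 2 & 4 h
animals (≈ +0.005 min⁻¹), near zero at 8 h, and negative for the 12 & 24 h
animals (≈ −0.004 min⁻¹), with the early-vs-late ANOVA contrast significant
for `Ktrans`. Individual stages are also exposed
(`dcepk simulate|t1fit|conc|pkfit|select|adc|stats`).

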