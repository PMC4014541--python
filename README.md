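# bolusflux

Whole-body glutamine kinetics from a stable-isotope **tracer bolus injection**.

Endogenous glutamine production matters clinically — plasma glutamine
depletion in critically ill patients predicts outcome — but the conventional
measurement, a primed continuous tracer infusion to isotopic steady state,
ties up a patient for hours. The bolus alternative injects a single dose of
[1-¹³C]glutamine, samples arterial blood densely for 90 minutes, and reads
the whole-body rate of appearance off the enrichment decay curve with a
single-pool model:

```
Ra = Dose / AUC              [µmol · kg⁻¹ · min⁻¹]
endoRa = Ra − exogenous glutamine delivery rate
```

where `Dose` is the injected tracer (µmol/kg) and `AUC` is the area under
the atom-percent-excess (APE) versus time curve, APE as a fraction. When
glutamine is also supplied intravenously (e.g. as the alanyl-glutamine
dipeptide), the known delivery rate is subtracted to obtain the endogenous
rate of appearance, endoRa.

The package is aimed at clinical-physiology groups running (or planning)
such tracer protocols. It provides:

- **enrichment** — raw GC-MS ion-ratio input (m/z 432/431), baseline
  correction, APE in mole-fraction or tracer/tracee-ratio convention,
  isotope-dilution concentrations via a [¹³C₅]glutamine internal standard
  (m/z 436), limit-of-quantification flagging;
- **kinetics** — explicit AUC decomposition (trapezoid or log-trapezoid
  observed area + OLS log-linear terminal tail extrapolation `C/k`), dose
  and infusion stoichiometry, Ra and endoRa;
- **protocol** — sampling schedules (the reference protocol: every 30 s to
  10 min, every 1 min to 30 min, every 3 min to 90 min; 60 samples), curve
  subsampling, and a sensitivity analysis quantifying what coarser or
  shorter protocols would have concluded;
- **synthetic** — one- and two-pool bolus simulators with known ground
  truth and multiplicative lognormal measurement noise (analytical CV
  4.1 % by default), so every estimator property is testable without
  subject data;
- **stats** — analytical and between-visit coefficients of variation,
  paired t-tests, one-way ANOVA with Dunnett many-to-one comparisons
  against a control group.

## Worked example

Simulate a five-subject post-absorptive cohort (true Ra drawn from
N(6.1, 0.9) µmol/kg/min, 4.1 % measurement CV) and analyse it:

```
$ bolusflux simulate --out sim --seed 7 --n-subjects 5
$ printf 'ape.convention: ratio\n' > config.yaml
$ bolusflux analyze --input sim/samples.csv --config config.yaml --out run
```

`run/results.csv` (columns abridged):

```
subject_id  auc_observed  auc_tail  auc_total    ra  endo_ra  tail_k_per_min
       S01       304.948    22.755    327.703 6.222    6.222           0.029
       S02       325.512    28.828    354.340 5.754    5.754           0.028
       S03       309.208    23.846    333.054 6.122    6.122           0.029
       S04       318.750    24.296    343.047 5.943    5.943           0.030
       S05       319.033    24.574    343.608 5.934    5.934           0.030
```

Reading S01: the observed APE area over 0.5–90 min is 305 %·min and the
fitted terminal exponential (k ≈ 0.029 min⁻¹) adds 23 %·min beyond the last
quantifiable sample, so `Ra = 20.39 µmol/kg / 3.277 = 6.22 µmol/kg/min`.
No infusion was declared (`exo_rate = 0`), hence `endo_ra = ra`. The
generator's truth table (`sim/truth.csv`) lists the true values 6.10, 5.68,
5.99, 5.83, 5.84 — each recovered to within ~2 %, with the small positive
offset expected from the area missed before the first sample at 0.5 min.

Declaring the 25 mg/kg/h alanyl-glutamine infusion
(`infusion.rate_mg_per_kg_per_h: 25`, `infusion.stoichiometry: 1`) shifts
every endoRa down by exactly 25/217.22 × 1000/60 = 1.918 µmol/kg/min.

The other subcommands: `bolusflux protocols` re-estimates endoRa under a
family of degraded sampling schedules and reports paired comparisons
against the reference protocol; `bolusflux stats` aggregates a tidy
per-subject endoRa table into group means with Dunnett comparisons against
a named control. Every output directory contains a `manifest.json` (config
snapshot, input digests, version, seed) and identical inputs reproduce
byte-identical result CSVs.

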