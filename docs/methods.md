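# Methods

## The single-pool bolus estimator

After an intravenous bolus of `Dose` µmol/kg of labelled glutamine into a
well-mixed pool turning over at rate `Ra`, tracer leaves the pool in
proportion to its enrichment, so the complete time integral of the
tracer/tracee ratio satisfies

    ∫₀^∞ r(t) dt = Dose / Ra        ⇒        Ra = Dose / AUC.

The estimator implements exactly this ratio (non-compartmental) identity.
It requires an overall metabolic steady state of the tracee, but — unlike a
primed continuous infusion — no isotopic plateau, which is what makes the
90-minute bolus protocol attractive for repeated clinical measurements.
When glutamine is delivered exogenously at a known, steady rate (an
alanyl-glutamine infusion running for hours before and through the
measurement), that delivery is part of `Ra` and is subtracted to give the
endogenous rate, `endoRa`. The bolus tracer itself is not part of the
subtraction: it is the numerator of the equation, not a steady infusion.

### AUC decomposition

The complete integral is not observable; the package makes each missing
piece explicit:

* **Observed area** (first to last usable sample): linear trapezoid by
  default, log-trapezoid optionally. On the dense reference schedule the
  trapezoid error for realistic decay rates (k ≲ 0.04 min⁻¹, 3-min spacing
  at worst) is below 0.15 % — under the analytical noise floor — so the
  simpler rule is the default. Log-trapezoid segments fall back to linear
  wherever an endpoint is non-positive or the two endpoints are equal.
* **Terminal tail** (beyond the last quantifiable sample): ordinary least
  squares of ln(APE) on time over the last `n_tail = 10` quantifiable
  points; the extrapolated area is `C_last / k`. Extrapolation is on by
  default and reported separately (`auc_tail`), so truncated and
  extrapolated analyses are always distinguishable. Points below the limit
  of quantification (default 0.01 % APE) never enter the fit; non-positive
  points inside the window shrink it with a warning; a non-decaying fitted
  slope is an error, never silently accepted.
* **Leading edge** (before the first sample at 0.5 min): deliberately *not*
  reconstructed. The peak can never be sampled at its true maximum, the
  measured AUC is therefore slightly too small, and the estimate is a
  small, systematic overestimate of `Ra`. Keeping that property fixed —
  rather than back-extrapolating a model-dependent peak — keeps the
  estimator definition identical across sampling protocols; an optional
  triangular head correction exists for sensitivity analyses only. At the
  default conditions (k ≈ 0.03 min⁻¹, first sample 0.5 min) the missed head
  is ≈ 1.5 % of the total area.

### Enrichment conventions

Two APE definitions are supported through one switch shared by the
enrichment parser and the simulator: the difference of isotopomer **mole
fractions** (exact isotope bookkeeping, the default when parsing raw GC-MS
ratio data) and the difference of **tracer/tracee ratios**. The two agree
to < 0.05 % absolute below ~2 % enrichment and diverge as enrichment grows.
The dilution identity `Ra = Dose/AUC` is exact for the *ratio* form, so all
ground-truth validation and simulation work uses the ratio convention
end-to-end; mixing conventions between generator and analysis is the one
configuration the shared switch exists to prevent.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| dose | 3 | mg/kg | dose-finding optimum: quantifiable ≥ 60 min, minimal concentration perturbation |
| tracer molar mass | 147.14 | g/mol | [1-¹³C]glutamine |
| isotopic purity | 1.0 | — | supplier certificate values can be set per lot |
| Ala-Gln molar mass | 217.22 | g/mol | Ala 89.09 + Gln 146.15 − H₂O 18.02 |
| Ala-Gln stoichiometry | 1 | mol Gln / mol | one mole of dipeptide delivers one mole of glutamine |
| LOQ | 0.01 | % APE | delimits the tail-fit window on decaying curves |
| `n_tail` | 10 | points | 27 min of the 3-min phase: enough leverage for k, still inside the terminal phase |
| AUC method | linear | — | see above |
| extrapolation | on | — | truncation-vs-extrapolation differences must be explicit, never implicit |

## The synthetic generator

The generator is the package's ground-truth instrument; its defaults encode
the study conditions.

**One-pool model.** `r(t) = (dose/q) · exp(−(Ra/q)·t)` with `q` the
effective rapidly exchangeable glutamine distribution pool, default
**200 µmol/kg**. This value is chosen so the simulated decay matches the
bolus method's operating regime: terminal k ≈ 0.03 min⁻¹, enrichment
quantifiable across the whole 90-min window, and a pre-first-sample head of
~1.5 % of the AUC — the "small overestimation" regime in which the method
is used. It is an *effective* volume: plasma alone (~20 µmol/kg) would give
a 2-minute half-life inconsistent with observed 90-min decay curves,
because real curves reflect rapid exchange with extravascular pools.

**Two-pool model.** A plasma pool (default 20.7 µmol/kg — chosen so a
3 mg/kg bolus roughly doubles the plasma glutamine concentration, as
observed in dose-finding) exchanging bidirectionally with a slow tissue
pool (default 300 µmol/kg, exchange 0.3 min⁻¹; skeletal muscle holds most
free glutamine). Solved in closed bi-exponential form (validated against a
matrix-exponential oracle at 1e−8 and mass-conserving to 1e−9). Its
complete plasma AUC still equals `dose/Ra`, so it isolates what a *finite*
window does to the estimate: with truncation the single-pool estimate
overestimates `Ra`, and over moderate exchange rates (0–0.3 min⁻¹ at the
defaults) the bias grows with the exchange rate. At stronger exchange the
terminal eigenvalue speeds up again and the bias surface turns over — the
direction is documented by the tests rather than assumed monotone
everywhere. Either way the bolus estimate is best read as glutamine
transport through the sampled pool rather than total production. The
two-pool defaults are illustrative: no quantitative human two-pool
parameters are established.

**Noise.** Multiplicative lognormal with median 1 on the enrichment excess,
CV 4.1 % (the duplicate GC-MS analysis figure). Cohort files emit baseline
rows at the calibrated natural background (default ratio 0.04) without
noise: the stated noise model acts on enrichment, and a noisy baseline
would add a coherent offset across all 60 samples — a real assay
failure mode, but not part of the measurement-repeatability model here
(see limitations).

**Replicate visits.** Repeatability designs (4 subjects × 2 visits) draw a
per-visit true Ra as the subject's value times a lognormal day-to-day
factor, CV **5 %**. The study-level observable this reproduces is the
between-visit CV of endoRa (~5.5 %): analytical noise on 60 points averages
down to only ~1–2 % on the AUC, so almost all between-visit variation must
be physiological; 5 % biological + propagated analytical noise lands the
pooled within-subject CV at ~5.2–5.5 %.

What the generator does *not* emulate: within-bolus concentration
transients (non-steady tracee during the first minutes), baseline drift and
calibration error, inter-subject differences in pool size independent of
Ra, correlated (chromatographic batch) measurement error, and any feeding
or insulin dynamics. Passing recovery tests therefore demonstrate estimator
correctness under the stated kinetic and noise model, not robustness to
every assay pathology.

## Statistics

* `cv_percent`: 100·SD/mean (sample SD); `within_subject_cv`: root mean
  square of per-subject CVs (the pooled repeatability CV for few-occasion
  designs). Whether a published between-study CV is pooled-within-subject
  or a CV of differences is often ambiguous; pooled-within-subject is the
  default here and the per-subject CVs are available for any other pooling.
* Paired t: standard two-sided Student's t for paired samples; a
  zero-variance difference vector is flagged degenerate (t = 0, p = 1 for
  identical lists) instead of propagating NaN.
* Dunnett many-to-one comparisons: multivariate-t formulation (exact
  correlation ½ in the balanced case, generalised for unbalanced n) via
  `scipy.stats.dunnett`, seeded for reproducible quasi-Monte-Carlo
  rectangle probabilities. For vectorised simulation studies a balanced
  critical value is exposed (`dunnett_critical_value`, by root-finding on
  the multivariate-t CDF); the test suite verifies that the max|T| rule and
  the full procedure make identical rejections. All tests are two-sided at
  α = 0.05.

## Numerical and design choices

* Times are matched to schedule grids within 1e−6 min — schedules address
  exact decimal grid points, not nearest neighbours.
* Negative post-baseline APE values (noise around zero) are retained in
  non-extrapolated AUCs; clamping would bias the area upward. They are
  excluded (with everything below the LOQ) from tail fitting.
* With extrapolation on, the observed area runs to the last *quantifiable*
  point and the fitted tail covers everything beyond it, so no interval is
  counted twice and `auc_total = auc_observed + auc_tail` holds exactly.
* Protocol-sensitivity p-values use the paired t across subjects per
  schedule versus the reference; failed cells (e.g. a schedule whose grid a
  curve lacks) become NaN and are excluded pairwise rather than aborting
  the analysis.
* Simulation sizes in the test and acceptance runs (5-subject cohorts,
  20 replicated repeatability studies, 10⁴ Dunnett null datasets) are the
  smallest that hold Monte-Carlo error comfortably below the tolerances
  being asserted.

## Known limitations

* The single-pool estimate is a plasma-pool throughput, not total-body
  production, whenever slow pools exchange appreciably; the two-pool
  simulator quantifies the direction and size of that gap.
* Baseline (natural-abundance) measurement error is not part of the noise
  model; in real assays a mis-estimated baseline shifts the whole APE curve
  coherently and the error does not average out over samples.
* No natural-isotope-abundance matrix correction for multi-label tracers;
  the package targets single-label (M+1) designs.
* The alternative-schedule family ships the three realistic degradation
  axes (peak frequency, tail frequency, tail duration); it is a
  representative family, not an exhaustive protocol search.
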