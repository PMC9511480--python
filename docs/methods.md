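# Methods

This note documents the models behind `maldiscreen`, the defaults it ships
with and why, what the synthetic data does and does not emulate, and the
numerical choices that matter when reproducing its outputs.

## The assay model

### Intraspectral biomarker ratio

Whole-cell linear-mode MALDI-TOF spectra (*m/z* 2000–20,000) of monocytic
cells carry phenotype biomarker peaks at *m/z* 4632 (resting marker) and
*m/z* 4964 (TLR-stimulation marker); a third feature at *m/z* 6891 falls
with stimulation but is more variable between replicates, so it is
quantified and reported without entering the decision statistic.

The decision statistic is the intraspectral area ratio

    r = A(4964) / A(4632)

computed per spectrum after preprocessing. Because both areas come from the
same spectrum, any overall intensity normalization (relative peak area over
the spectrum total, TIC scaling, laser-power drift) cancels in the
quotient. Whether the original relative-peak-area normalization divided by
the total ion current or by the two-feature sum is immaterial for exactly
this reason: every such variant yields the same ratio, ordering and
decisions. Per plate, ratios are divided by the mean ratio of the
stimulated negative-control wells, so the full inflammatory phenotype
centers at 1; an inhibited (resting-like) well falls toward r_rest/r_stim ≈
1/3 under the default generator.

### Percent effect and screen QC

A test well's percent effect rescales its normalized ratio between its own
compound set's controls:

    effect = 100 · (neg − r) / (neg − pos)

with `neg` the stimulated negative-control mean (0% = no effect) and `pos`
the full-inhibitor positive-control mean (100% = complete inhibition).
Controls are per set because the screen staggers compounds into 8 sets,
each with its own control pair. Hit calling takes the mean effect over the
three biological replicates against a 40% cutoff (ties included; a strict
per-replicate mode is available via `call_hits` on individual replicate
columns). Z′ = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg| is computed per set
from control values (one per biological replicate after technical
averaging, sample SDs) and summarized as the across-set mean; reporting a
single assay-level Z′ leaves the across-set aggregation unstated, so the
mean was chosen and the per-set values are always reported alongside.
Replicate reproducibility is the squared Pearson correlation of
per-compound effect vectors between biological replicates, averaged over
the three pairs.

### Preprocessing chain

Fixed order: resample (linear interpolation, 1 Da grid) → top-hat baseline
subtraction → Savitzky–Golay smoothing. The top-hat baseline is the
grayscale opening (moving minimum then moving maximum, flat structuring
element, edge replication, window forced to an odd point count); opening is
idempotent, never exceeds the signal, and reconstructs the input exactly
when added back. The default 400 Da window is two orders above the peak
FWHM, so narrow-peak areas survive within 1%. Savitzky–Golay uses window 9,
order 3 with polynomial edge handling; window 1 is the identity. Feature
integration is trapezoidal over a closed window of half-width
max(5 Da, 0.001·m/z); binned fingerprints use half-open 5 Da bins
normalized to unit total. SNR for peak picking is apex over 1.4826·MAD of
the surrounding ±100 Da (excluding ±3σ of the peak), threshold 3. The original
vendor-processing window sizes are not documented anywhere usable; all are
config-exposed.

### PCA fingerprinting

PCA operates on mean-centered TIC-normalized binned vectors (no variance
scaling — bins are on a common scale and variance scaling would inflate
empty regions). Component signs follow the convention that the
largest-magnitude loading is positive. The "separating component" between
two condition groups is the one with the largest standardized mean score
difference; the loading plot of that component is how the biomarker bins
are (re)discovered in the synthetic data.

### Group comparison

Two-sided Mann–Whitney U, exact by null-distribution enumeration when both
groups are tie-free with min(n) ≤ 8, otherwise the tie- and
continuity-corrected normal approximation. An all-identical comparison
returns p = 1. Note the exact and asymptotic p at n = 8/8 can differ by up
to ~0.011 at central U values; the tests pin typical agreement at ≤ 0.01.

## Thermal profiling model

Soluble fraction after heating to temperature T:

    f(T) = (1 − p) / (1 + exp(b − a/T)) + p,   a > 0, b > 0, 0 ≤ p < 0.5

with Tm the half-denaturation point f(Tm) = 1/2:

    Tm = a / (b − ln(0.5 / (0.5 − p)))    (= a/b when p = 0).

The 1/T term uses the input's temperature unit, making (a, b)
unit-dependent while the recovered Tm is not (verified to 0.1 °C on
noiseless °C↔K conversions). Fitting is bounded least squares with
multi-start on b ∈ {8, 15, 25, 40, 60}; monotone-increasing or flat traces
return `converged=False` rather than a spurious Tm.

Normalization of a protein × temperature table: each trace is scaled to 1
at the lowest temperature; curves with preliminary fit R² > 0.8 and plateau
< 0.3 form the normalization set; the sigmoid fitted (with a free overall
scale — the per-trace scaling takes curves a hair outside the pure sigmoid
family) to the reference condition's per-temperature medians defines the
target, and per-(condition, replicate, temperature) factors map each
sample's medians onto it.

The target-engagement hit rule between two drug conditions: all four
replicate pairs fitted, per-replicate ΔTm sign-consistent, |mean ΔTm| ≥
2 °C and SD(ΔTm) < 2 °C. The sign-consistency + magnitude clause
operationalizes "changed significantly in all replicates" — the original
workflow's exact test is not restated anywhere usable — while the SD
clause is applied verbatim. On identical-condition null simulations the
rule fires on < 5% of proteins.

ITDR (isothermal dose–response at one temperature, 56 °C in the validation
experiments): soluble fraction follows the rising logistic
b0 + (bmax − b0)/(1 + (EC50/c)^h). The fit uses relative (constant-CV)
weights, plateau bounds [0, 1.2] (the response is a fraction), and an EC50
multi-start grid over the observed concentrations. With ≤ 5 distinct
concentrations the Hill slope is fixed at 1: four free parameters on five
points are unidentifiable, and the five-point design stops at ~2× EC50
where bmax and EC50 trade off freely. A single five-point series at 10%
relative noise carries a Cramér–Rao lower bound of ~42% relative SE on
EC50, which is why the simulated experiment follows the four-replicate
design of the corresponding wet-lab workflow and why summary numbers are
medians over repeated simulated experiments.

## The synthetic-data generator

The generator is the package's substitute for raw instrument data and
defines the conditions every downstream number is computed under.

A spectrum is: three biomarker Gaussians (areas 200/150/100 at rest;
LPS multipliers 0.6 / 1.8 / 0.5 for 4632/4964/6891, giving the observed
directions and a 3-fold stimulated/resting ratio shift; further multipliers
for Pam2CSK4, Pam3CSK4, IFN-γ and an apoptosis-like fingerprint), plus 30
background Gaussians with config-fixed positions (a shared biological
background fingerprint), an exponentially decaying chemical baseline
(amplitude 200, decay 1500 Da), and noise. Peak width follows the
linear-mode resolution model σ = m/z / 2000 (≈ 850 FWHM resolving power).
Inhibitors pull every condition multiplier toward 1 in proportion to their
inhibition fraction.

The noise model has four parts, and their split is the scientifically
load-bearing choice: a whole-spectrum log-normal scale factor (CV 0.25)
that models shot-to-shot MALDI intensity variation and cancels exactly in
the intraspectral ratio; independent per-peak log-normal area factors
(CV 0.015); additive Gaussian grid noise (SD 0.3); and m/z jitter
(SD 0.3 Da). Raw biomarker CVs are not reported anywhere; the per-peak CV is
calibrated once so that the default screen's assay window lands at the
reported quality level (Z′ ≈ 0.8–0.9, replicate R² ≈ 0.85–0.9 — the
replicate-R² bound binds, because percent effect inherits correlated noise
from the single per-set control pair). These defaults were frozen before
the acceptance analyses and are not tuned per run.

The screen simulation mirrors the campaign design: 96 compounds in 8 sets,
per-set NG-25-like positive (full inhibitor) and MRT68601-like negative
(non-inhibiting) controls, technical triplicate spectra, three biological
replicate plates, 5 µM test concentration, and two seeded actives
(inhibition fractions 1.0 and 0.92). Dose series parameterize the
*measured* percent-effect curve: because the ratio is a nonlinear function
of the inhibition fraction, the generator inverts that map in closed form
so a reported (measured-scale) IC50 of 450 nM is what the pipeline should
recover.

TPP simulation: per-replicate true Tm jittered by 0.5 °C (biological
replicate variation — small enough that the SD < 2 °C rule is satisfiable
by true hits, which is what the rule presumes), traces evaluated at the
8-point 40–68 °C ramp and multiplied by 10% log-normal noise, relative to
the lowest temperature. Melt-shape parameters b = 25, p = 0.02 (transition
width ≈ 8 °C) are field-typical; the original experiments' fitted shape
parameters are not available, so presets anchor the reported Tm and ΔTm
values instead: p38α 50.8 → 56.8 °C (ΔTm +6), MK3 51.0 →
53.5 °C (ΔTm +2.5), CETSA 50.3 / 50.2 / 60.7 / 50.8 °C for
DMSO/LPS/nilotinib/imatinib, ITDR EC50 4.6 µM between plateau fractions
0.1 and 0.9.

What the generator does **not** emulate: detector saturation, m/z-dependent
calibration drift, matrix crystallization heterogeneity and spot-position
effects, plate-edge effects, isotope envelopes, chemical adducts, TMT
reporter-level noise and protein-inference ambiguity, or compounds that are
cytotoxic rather than inhibitory. Passing tests therefore demonstrate that
the analysis chain recovers what it is supposed to recover under the
assay's characterized statistical regime — not that the pipeline is robust to
every artifact of real instrument data.

## Problem sizes

Summary analyses use: 20 simulation seeds for the screen metrics (each
seed = 1008 spectra of 18001 points); 5 repeated experiments for each
TPP/CETSA recovery (each = 4 replicates × 2–4 conditions × 8 temperatures);
9–15 repeated four-replicate ITDR experiments; 3 seeds for the dose series.
Stochastic summary values are medians across those repeats; the
per-experiment designs themselves (replicate counts, temperatures,
concentrations, noise levels) follow the original experimental layout.

## Known limitations

* The mzML layer is a compact reader/writer pair covering profile-mode
  spectra with 32/64-bit float arrays, zlib or no compression; exotic
  encodings (numpress) and vendor raw formats are out of scope.
* No m/z recalibration or cross-spectrum alignment; biomarker windows
  assume calibrated axes (jitter ≲ 1 Da).
* No spatial plate-effect correction (row/column normalization).
* The TPP hit rule is a documented surrogate for the original workflow's
  unstated significance test; its false-positive behaviour is characterized
  on null simulations only.
* Melt fits assume the two-state sigmoid; proteins with biphasic melting
  or strong aggregation artifacts will simply fail to converge.
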