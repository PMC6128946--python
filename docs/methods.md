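# Methods

`nirscart` implements an arthroscopic near-infrared spectroscopy (NIRS)
analysis chain for articular cartilage and subchondral bone: synthetic study
generation, spectral preprocessing with probe-contact quality control,
shallow-network calibration trained by Levenberg-Marquardt (LM) with greedy
forward wavelength selection, and nonparametric evaluation. This note
records the models, the parameters that matter, the numerical choices, and
the limits of what the synthetic experiments demonstrate.

## Study model

The simulated study mirrors a two-group equine design: `n_repair` ponies
carry surgically repaired chondral lesions (two lesions per joint, two
femoropatellar joints per pony) and `n_control` ponies are healthy. Twelve
measurement locations surround each (putative) lesion site, grouped into
four distance classes of three locations each, class 1 adjacent to the
lesion. A configurable number of locations (default 4, drawn among repair
ponies under the design seed) is arthroscopically unreachable and excluded
from both modalities. With the default 7 repair + 3 control ponies this
yields 236 measured locations in vitro and 164 arthroscopically (control
ponies are never arthroscoped), 28 lesions, and — after the 60/30/10
pony-level split — a 24-location test group.

### Latent tissue state and reference properties

Each location draws a latent state: water fraction (healthy mean 0.72, SD
0.03, clamped to [0.60, 0.85]), collagen density (1.00 ± 0.10), proteoglycan
density (1.00 ± 0.15), mineral density (1.00 ± 0.12) and a scattering slope
(0.50 ± 0.05). The ten reference properties are deterministic monotone
functions of the latent state: each property is

    property = mean * softplus(1 + u) / softplus(1) / normaliser,

where `u` is a weighted sum of standardised latent deviations and the
normaliser (Gauss–Hermite quadrature over the healthy latent distribution)
centres the healthy population exactly on the nominal means (E_eq 579 kPa,
E_dyn 7.25 MPa, plate BV 98.4 %, plate BMD 1.00 g/cm³, plate thickness
174 µm, trabecular BV 30.5 %, BMD 0.247 g/cm³, thickness 169 µm, SMI 0.367,
cartilage thickness 1000 µm). Plate BV is bounded by mapping the deficit
(100 − BV) instead; SMI is linear in mineral density and may go negative
(plate-like architecture). Monotonicity makes recovery testable: any
estimator that tracks the latent drivers must track the properties.

Repair-group degeneration shifts the latent means — water up (+1.3 SD),
proteoglycan (−2.0 SD), collagen (−1.5 SD) and mineral (−1.7 SD) down at
distance class 1 — decaying linearly with distance class (class k of 4
receives a fraction (4 − k + 1)/4 of the shift). The overall `scale` knob
multiplies all shifts; `scale = 0` reproduces the healthy distribution
exactly. These magnitudes were chosen once to produce clearly separated
group distributions near the lesion (Mann-Whitney power ≈ 1 at the default
design) and graded differences across distance classes.

### Spectral forward model

Each acquisition covers two spectrometer arms: 0.35–1.10 µm in 1251 channels
(0.6 nm) and 1.00–2.50 µm in 235 channels (6.4 nm). Intensity (normalised to
a unit dynamic range) is a linear scattering baseline (slope tied to the
scattering latent and mineral density) minus truncated-Gaussian absorption
bands: water at 0.97/1.45/1.93 µm (depths 0.06/0.30/0.80, scaled by water
fraction), CH overtones at 0.90/1.18/1.73 µm (scaled by collagen), NH at
1.00/1.50 µm (scaled by proteoglycan). Bands are truncated at ±3σ so each
has compact support — band-level claims ("this change is confined to the
water bands") are then exactly testable. Channels ≥ 1.90 µm are pinned to
95 % of dynamic range plus 5× noise (detector saturation by water
absorption); only the unusability of that region matters downstream.

Arthroscopic acquisitions add two artefacts. Probe contact quality `c` per
repeat is Beta-distributed (mode 0.85, concentration 10); it attenuates all
band depths by the factor `c` and inflates the additive noise by
(1 + 2(1 − c)). Arthroscope-light contamination is a raised-cosine bump
exactly confined to 0.42–0.75 µm whose level couples to poor contact
(×(1 + 3(1 − c))). The per-location base light level is exponential with
mean 2×10⁻⁴: faint leakage when contact is good, so that under the
contamination threshold below ordinary locations are retained while
deliberately contaminated locations (the `contaminated_locations` option,
default level 0.05) are excluded — reproducing a study in which only a
handful of locations were lost to light contamination. In vitro acquisitions
have perfect contact, zero light, and 3 repeats versus 15 arthroscopic.

The full dataset is a pure function of (design, effect, acquisition, seed);
per-location substreams come from a spawned `SeedSequence`, so regeneration
is bit-identical.

What the generator does **not** emulate: radiative transfer or
wavelength-dependent penetration depth, instrument response functions,
repair-tissue (hydrogel) spectra, inter-joint correlation within a pony, and
baseline shapes richer than an affine trend. Passing recovery tests
therefore demonstrates that the pipeline extracts monotone latent signal
from band depths under the modelled artefacts — not that it would reach the
same accuracy on real arthroscopic data.

## Preprocessing

Third-order Savitzky-Golay smoothing is applied per arm: windows (25, 13)
samples for cartilage-target models and (45, 13) for bone-target models
(arm A, arm B respectively). Edges use a least-squares polynomial fitted to
the terminal full window rather than padded data. The arms are merged at
1.00 µm — arm A supplies channels below, arm B from 1.00 µm — so every
wavelength has one authoritative channel; the merge point is the single
permitted resolution discontinuity. Channels ≥ 1.90 µm are always dropped;
analysis regions are 0.40–1.90 µm (wide) and 0.75–1.90 µm (NIR-only).

**Contact-quality statistic.** For each arthroscopic spectrum the area
between the smoothed arm-A spectrum and the straight line through its
values at the channels nearest 0.42 and 0.75 µm is computed (trapezoidal
integral of the absolute deviation). The absolute (unsigned) deviation is
used; the statistic is computed on smoothed intensities (window 25), both
package choices where the construction admits alternatives. Per location the
8 of 15 repeats with the smallest area are retained (ties broken by earlier
repeat index); in vitro repeats are simply averaged. A location is excluded
when the median retained area exceeds a threshold, by default 3 robust
standard deviations (1.4826 × MAD) above the median of the study-wide in
vitro area distribution. The coefficient of variation between paired
arthroscopic and in vitro mean spectra (population SD/mean per channel,
averaged over 0.75–1.90 µm, in percent) is reported as a QC summary.

## Network and training

The regression model is a single hidden layer of 1–8 tanh units with a
linear output. Inputs and targets are min-max scaled to [−1, 1] using the
calibration set only (leakage guard; validation/test/arthroscopic data never
touch the scaling). Training is full-batch Levenberg-Marquardt: per epoch
solve (JᵀJ + µI)Δw = Jᵀe with the analytic model Jacobian; a step is
accepted only if training SSE decreases, otherwise µ is multiplied by 10 and
the solve retried; on acceptance µ is multiplied by 0.1. Defaults
µ₀ = 10⁻³, cap 10¹⁰ (classic Marquardt schedule). Training stops at the
epoch budget, on damping overflow, or — the usual path — after 6 consecutive
epochs without a new validation-SSE minimum; the best-validation weights are
returned, not the last. An "iteration" in the early-stop rule is one
full-batch LM epoch (LM is inherently full-batch). Initialisation is
Nguyen-Widrow-style scaled uniform, seeded; `n_restarts` independent
initialisations are run (default 3) and the restart with the lowest
validation SSE wins. Degenerate (zero-variance) targets return a constant
predictor with a warning.

## Wavelength selection

Greedy forward selection over a strided candidate grid of processed
channels. Three variants: Model 1 (0.75–1.90 µm, criterion = arithmetic mean
of the test-group NRMSE and the arthroscopic NRMSE), Model 2 (0.75–1.90 µm,
test NRMSE), Model 3 (0.40–1.90 µm, test NRMSE). The arithmetic mean is the
package's combination rule for Model 1 (scale-free, equal weight — NRMSEs
are already normalised). Candidate subsets are scored with a reduced budget
(default 15–20 epochs, one restart, 3 hidden units); after selection stops
(variable budget reached, or `patience` consecutive additions without a new
best criterion), the best-so-far subset is retrained fully with a hidden-
unit grid search (1–8) on validation RMSE. The reported criterion trajectory
is the best value attained at each subset size, hence non-increasing.
Arthroscopic spectra enter only through the Model 1 criterion and final
evaluation — never weight fitting.

Using the test group inside selection reproduces the original analysis
protocol faithfully, but it is optimistic: test-set metrics for the selected
model are not unbiased estimates of generalisation error. The library
defaults use stride 8 and a budget of 12 variables so that a full 9-parameter
× 3-variant run completes in minutes on one CPU; stride 1 and a budget of
220 are supported where per-channel granularity is wanted.

## Evaluation

RMSE; NRMSE = 100 × RMSE / (max − min) of the measured values pooled over
the in vitro reference sets (the package's reading of "reference parameter
range"; arthroscopic data are excluded from the range); RPIQ =
IQR(measured)/RMSE with type-7 (linear interpolation) quantiles, flagged
reliable at RPIQ ≥ 2, reported as +∞ when RMSE is zero. Arthroscopic
per-location predictions are the mean of the non-negative per-spectrum
predictions of the 8 retained repeats; a location where every prediction is
negative is reported missing and excluded (not clamped to zero). Spearman
correlation uses average ranks; its two-tailed p-value is exact (full
permutation enumeration) for n ≤ 8 and t-approximated beyond — the exact
cutoff is set at 8 because full enumeration at n = 9–10 costs five orders of
magnitude more for an informational p-value. Mann-Whitney U is exact for
tie-free samples with both groups ≤ 8 and otherwise uses the tie-corrected
normal approximation with continuity correction. A Shapiro-Wilk gate is
informational only: the pipeline's group comparisons are nonparametric
regardless.

## Indentation mechanics

Reference moduli come from a simulated indentation rig: four 5 %-strain
stress-relaxation steps (ramp 100 %/s, 600 s holds) then 1 Hz sinusoidal
loading at 1 % strain amplitude, with a plane-ended cylindrical indenter
(d = 0.53 mm). The material model is a standard linear solid, E(t) = E∞ +
E₁·exp(−t/τ) (default τ = 5 s), with exact piecewise-analytic stress
solutions for ramps and the sinusoid (start-up transient included).
Equilibrium stress per step is the mean over the final 10 % of each hold;
E_eq is the slope of equilibrium stress vs. strain over the contiguous run
of ≥ 2 steps maximising fit R² (ties favour longer runs, R² compared at
6 decimals because two-point fits are exactly 1), converted with ν = 0.1.
E_dyn is the stress/strain amplitude ratio from least-squares sinusoid fits
at the protocol frequency (first 3 cycles skipped), converted with ν = 0.5.
The indentation-geometry correction is a pluggable scalar κ (default 1)
applied symmetrically in simulator and extraction — the package deliberately
does not hard-code an aspect-ratio correction table, so absolute moduli are
exact only relative to the chosen κ.

## Pipeline and problem sizes

The orchestrated run simulates (or loads) a study, applies QC, splits at
pony granularity (60/30/10; the test pony is a fully measured repair pony;
controls are spread over calibration/validation), fits every
(parameter, variant) pair, and writes the report bundle (`report.csv`,
`qc.csv`, `group_summary.csv`, `group_comparison.csv`, per-model JSON,
`manifest.json` with seed, config hash and split). All randomness derives
from the single config seed, and report CSVs are byte-identical across
reruns.

Problem sizes used by the shipped experiments (the package's own choices
for quick, reproducible runs): default pipeline selection stride 8, budget
12, patience 4; the recovery experiments in the acceptance suite and
`scripts/acceptance.py` use stride 12, budget 6, patience 3, candidate
training 12 epochs, final grid {2, 4, 6} hidden units over 60 epochs, 10
replicate studies; statistical calibration uses 1000 null and 200
alternative replicate reference tables (reference draws only, no spectra).

## Known limitations

* Synthetic spectra are additive band models; none of the multiplicative
  scatter effects that motivate SNV/MSC correction are simulated (and no
  scatter correction is implemented — the modelling chain does not need it).
* Selection-time use of the test group (see above) means reported test
  metrics are optimistic for model selection purposes.
* The Beta contact-quality model and the light-contact coupling are
  plausibility stand-ins, not inferred from data; no per-repeat variance
  measurements exist to calibrate them against.
* The κ = 1 default leaves indentation moduli in "uncorrected slope" units;
  users with a validated aspect-ratio correction should supply it.
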