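# Methods

`petkin` quantifies receptor binding from dynamic small-animal PET
time–activity curves (TACs) using an image-derived arterial input — the
left-ventricle blood-pool curve — in place of arterial sampling. It targets
the study design in which α4β2 nicotinic-receptor radioligands with very
different kinetics (a slow, 180-min "2-FA"-like protocol and a fast, 60-min
"Nifene"-like protocol) are compared across wild-type (WT), β2-knockout
(KO) and acute-nicotine (AN) mice. This note records the model equations,
the numerical scheme, the synthetic-data design and the deliberate choices
made where the design was genuinely open.

## Compartment models and the measured signal

The two-tissue compartment model (2TCM) describes exchange between plasma
(concentration C_b, here whole blood from the left ventricle; no metabolite
correction, no plasma/whole-blood ratio), a free/non-specific tissue
compartment C_1 and a specifically bound compartment C_2:

    dC1/dt = K1 C_b − (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 − k4 C2

with K1 (ml plasma → ml tissue delivery, 1/min since 1 g ≡ 1 cc), k2
(efflux), k3 (binding) and k4 (dissociation). The tissue impulse response
is biexponential,

    h(t) = A1 e^(−α1 t) + A2 e^(−α2 t),
    α{1,2} = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4 k2 k4)]/2,
    A1 = K1 (k3+k4−α1)/(α2−α1),   A2 = K1 (α2−k3−k4)/(α2−α1),

and the measured region signal includes a fractional blood volume vp:

    C_model(t) = (1 − vp) (h ⊛ C_b)(t) + vp C_b(t).

The one-tissue model (1TCM) is the k3 = k4 = 0 nesting with h = K1
e^(−k2 t). The binding potential is BP_ND = k3/k4, and the distribution
volume ratio satisfies DVR = BP_ND + 1 under ideal reference-tissue
assumptions.

All times are minutes and all rate constants 1/min. Activity is either
kBq/cc or SUV (activity / (injected dose / body weight), dimensionless at
1 g/cc tissue density). Decay correction is assumed already applied during
reconstruction; the package neither applies nor removes it.

## Numerical scheme

The input curve is represented as a piecewise-linear interpolant anchored
at the frame midpoints and pinned to zero at t = 0 (an intraperitoneal
injection starts at zero blood activity); beyond the last midpoint it is
extrapolated as a constant. On a uniform grid whose step divides the frame
boundaries (0.25 min for minute-scale frames, finer for sub-minute frames),
convolution with each exponential mode is evaluated *exactly* per linear
segment through a first-order recurrence (evaluated with a linear filter,
so no Python-level loop), and the running integral of each mode follows
from Y = (∫u − y)/α. Frame values are the exact time-averages of the
continuous model over each frame — PET frames integrate counts, and this
matters for 10-s frames. Coincident eigenvalues (α1 = α2, e.g. k3 = 0 with
k2 = k4) switch to the analytic t·e^(−αt) limit with its own recurrence
rather than failing; α is floored at 1e−12 to avoid a separate α = 0
branch (error O(αT) ≈ 1e−10). Against a stiff LSODA integration of the
state equations driven by the same input, per-frame agreement is ~1e−10
relative (the test suite enforces ≤ 0.1% over random parameter draws).

## Fitting

`fit_compartment_model` minimizes the (optionally frame-duration-weighted)
sum of squared residuals with scipy's trust-region-reflective bounded
least squares, from `n_starts` (default 20) uniform random initial points
inside the bounds box — K1, k2, k3, k4 ∈ [0.0001, 5] 1/min, vp ∈
[0.0001, 0.3] — deterministic given the seed. The returned solution is the
lowest-WSS point over all completed starts, including starts that
exhausted the evaluation budget (their endpoint is still a valid
candidate; the `converged` flag reflects the winner's status). BP_ND is
reported with a reliability flag rather than clipped when k4 sits below
1e−3 (the ratio k3/k4 then explodes, which is exactly the instability
seen in low-binding groups). Model comparison uses the Gaussian-residual
AIC, n ln(WSS/n) + 2k; because the additive constant is dropped, AIC
values are comparable within this package only.

SRTM (simplified reference tissue model) fits C_T(t) = R1 C_R(t) +
(k2 − R1 k2a)(C_R ⊛ e^(−k2a t)) with k2a = k2/(1+BP), using the same
multi-start machinery (bounds R1 ∈ [0.01, 10], k2 ∈ [0.0001, 5],
BP ∈ [−0.95, 30]); the direct R1 term uses the measured reference frame
values so that a target identical to its reference is fit exactly by
R1 = 1, BP = 0. The derived reference efflux is k2′ = k2/R1. The Logan
reference-tissue plot regresses ∫C_T/C_T on (∫C_R + C_R/k2′)/C_T over
frame midpoints at T ≥ t*; integrals are trapezoids with a zero anchor at
t = 0, consistent with the input interpolation. t* is chosen automatically
as the earliest start for which no later point deviates from the segment's
own regression line by more than 10% (≥ 4 points retained, falling back to
the latest admissible segment with a logged warning). k2′ defaults to the
target region's own SRTM fit; a pooled-median option exists
(`PipelineConfig.pooled_k2_ref`).

A caveat the test suite documents explicitly: the Logan slope equals
BP_ND + 1 only after the slowest kinetic mode equilibrates (time scale
1/α1, ≈ 183 min for the slow-ligand wild-type thalamus). Within a 180-min
scan the ideal-reference DVR therefore still underestimates BP_ND + 1 by
several percent, and the consistency check runs on an extended schedule
where the identity holds to < 1%. With a realistic cerebellum reference
(k3 > 0) the DVR is strictly below BP_ND + 1 on the standard protocol —
the reference-tissue bias the image-derived input function avoids.

## Noise model

Frame-wise additive Gaussian noise with

    σ_i = level · C_max · (C_i/C_max)^a · (Δt_ref/Δt_i)^b,

defaults a = b = 1 and Δt_ref = 1 min: σ is proportional to the frame
amplitude divided by the frame duration, and the relative SD on a 1-min
frame equals `level` (default 0.2). The count-statistics alternative
σ ∝ √(C/Δt) is available via a = b = 0.5; exponents and reference duration
are echoed into study output so the convention in force is always
recorded. Negative noisy values are retained — clipping would bias the
mean, and the unbiasedness is tested. An alternative normalization that
pins 20% relative SD at the curve maximum of the longest frame was
evaluated and rejected: it implies several-hundred-percent noise on the
early short frames, under which the 5-parameter fit degenerates and the
recovery study cannot reproduce the truth-within-IQR behaviour this
design is meant to exhibit.

## Recovery study

`run_recovery_study` treats the noise-free fits as truth, then per
iteration (default 50) re-noises the blood, thalamus and cerebellum curves
independently, refits the 2TCM per region against the noisy blood curve,
and records all five parameters plus BP_ND — non-convergent iterations are
logged with their seeds, never dropped silently (the study aborts only
beyond 50% failures). Percentiles are computed over converged fits, and
`iqr_coverage` flags whether truth lies in [P25, P75]. The study seed
drives only the noise stream; multi-start points come from the fit seed
and are identical across iterations, so a zero-noise study collapses
exactly onto the noise-free fit. The packaged validation runs 50
iterations at level 0.2 with 6 starts per fit — enough to keep the
two-region study around two minutes on one CPU while leaving coverage
results unchanged relative to more generous settings (verified at 10
starts).

## Synthetic cohorts

The generator emulates the study's cohorts so the entire pipeline runs
without animal data. The blood input is a Bateman function
A(e^(−λe t) − e^(−λa t)) — the simplest shape with a delayed peak and slow
tail appropriate to intraperitoneal delivery — calibrated by closed form
plus two nested scalar root-solves so its frame-averaged curve reproduces
the published wild-type left-ventricle peak SUV (0.55 at a package-chosen
10 min for the slow ligand; 0.98 at 5 min for the fast one) and the mean
SUV over the final 30 min (0.077 and 0.41). The published late/peak
summaries showed no group differences, so all groups share the wild-type
targets. Per subject, rate constants are drawn from truncated normals
around the published group means (SDs as printed, truncated below at 10%
of the mean; the dispersion is a free scale factor since the printed
spread may be SEM rather than SD), vp from a truncated normal around 0.05
(SD 0.01) — a typical rodent cerebral blood-volume fraction, as the study
prints no vp. Each subject shares one input curve across regions, scaled
by a per-subject amplitude factor with the published peak relative SD.
Tissue TACs are produced by the package's own forward model driven by the
frame-sampled input, so noise-free refits recover each subject's constants
exactly — the intended baseline for the noise study. Files are written in
kBq/cc with drawn dose (≈7.4 MBq) and weight (≈25 g), so reading a cohort
exercises the SUV conversion.

What the generator does *not* emulate: reconstruction artifacts,
partial-volume and spill-in effects on the left-ventricle VOI, blood
metabolites, inter-parameter correlation within a subject, abdominal-fat
sequestration of the lipophilic ligand, and radioactive decay. Passing
tests therefore demonstrate correctness of the estimators on data obeying
the model assumptions, not robustness to those real-data effects.

## Group statistics

One-way ANOVA with post hoc Tukey HSD (statsmodels), η² = SS_between /
SS_total with a 95% CI by noncentral-F inversion (Steiger's method: the
confidence limits on the noncentrality λ map to η² = λ/(λ+df1+df2+1));
the paired BP_ND + 1 vs DVR comparison uses a paired t-test with an
infinite-t sentinel (and warning) for zero-variance nonzero differences.
Normality screening is reported descriptively and never gates the ANOVA.

## Known limitations

- AIC values use one fixed convention and are not comparable to values
  computed elsewhere with a different constant.
- BP_ND from low-binding data (k4 near its bound) is reported but flagged;
  its sampling distribution under noise is heavy-tailed, and the recovery
  study shows upward-skewed BP_ND spreads in low-binding configurations.
- The Logan DVR is intrinsically biased low for slow kinetics on short
  scans (see above) and whenever the reference region carries specific
  binding; the package reproduces, rather than corrects, this bias.
- The left-ventricle curve is treated as whole blood with no
  metabolite or partial-volume correction, matching the study design.
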