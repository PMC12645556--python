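# Methods

This note documents the models and estimators implemented in
`spinemetry`, the choices made where the design was genuinely open, and
what the synthetic-data suite does and does not establish about real
data.

## Coordinate convention

Right-handed mm coordinates: x = medio-lateral, y = dorso-ventral,
z = rostro-caudal.  The coronal plane is spanned by (x, z) — scoliosis
is read there; the sagittal plane by (y, z) — kyphosis is read there.
Vertebra indices are taken as given in the input (rostral→caudal file
order); no anatomical re-labelling is attempted.

## Spine centerline and curvature

Each vertebra's landmarks (typically 8) are collapsed to their
arithmetic centroid; the centerline is the per-coordinate cubic spline
through the centroid polyline, parametrized by normalized cumulative
chord length (uniform parametrization is available for sensitivity
checks).  Curvature and radius follow the Frenet formulas

    kappa(t) = ||gamma'(t) x gamma''(t)|| / ||gamma'(t)||^3,
    r(t) = 1 / kappa(t),

evaluated from the analytic derivatives of the stored piecewise cubics
on a uniform 512-point t-grid.  Radii where kappa < 1e-12 mm^-1 are
reported as +inf.  Arc length is the trapezoidal integral of
||gamma'||; scalar summaries are max kappa (smallest t on ties),
arc-length-weighted mean kappa, and total curvature ∫ kappa ds
(radians — the total tangent turning of a planar curve).

**Flat ends.**  The curve is constrained to have zero curvature at both
extremes (gamma'' = 0, hence gamma' x gamma'' = 0), which confines the
analysis to the annotated part of the column and suppresses spurious
end curvature where the spine would continue into head and tail.  A
plain natural interpolant through ~24 centroids lets this constraint's
transition region bleed about two vertebrae inward, which measurably
biases interior curvature (~4% on a 20 mm/60° arc) and understates the
Cobb angle of a single-arc deformity by ~0.9°.  `fit_spine_curve`
therefore imposes the constraint on a chord-refined knot grid: the
centroids are first interpolated by an unconstrained (not-a-knot)
cubic, every knot interval is subdivided 8×, and the natural spline is
built through the refined samples.  The boundary condition then holds
exactly, the curve still interpolates every centroid, and the measured
errors drop to 0.02% (interior kappa) and ~0.11° (Cobb).
`refinement=1` recovers the plain natural interpolant.

A bounded side effect remains: where the true end curvature is nonzero
(e.g. a fitted circular arc), kappa must rise from 0 and locally
overshoots the true value by up to ~25% inside the outermost chord
interval.  Interior profiles are unaffected; the max-kappa summary of a
nearly-constant-curvature spine reflects this transition, so mean or
total curvature is the recommended summary for group comparisons (mean
curvature is the default).

**Smoothing.**  `smoothing=0` (default) interpolates.  For noisy
landmarks, `smoothing>0` applies a P-spline-type penalty of difference
order 3 to the centroids before fitting: it damps knot-to-knot wiggles
while leaving quadratic — locally arc-like — trends unshrunk, so
deformity amplitude is preserved.  `DEFAULT_NOISY_SMOOTHING = 1e-7`
(units (mm / unit-parameter³)⁻²) suits landmark noise of 0.1–0.3 mm:
with 0.2 mm noise the recovered Cobb bias of ≥10° arcs is below 0.3°,
versus +3…5° for the interpolating fit (the maximum-divergence Cobb is
an extreme statistic, so unsmoothed tangent noise inflates it).  The
pipeline configuration (`RunConfig`) uses this value by default;
oracle tests on noise-free data use 0.

## Analytic Cobb angle

The clinical Cobb angle is measured between endplates of the most
tilted vertebrae; this package computes the standard automated
surrogate: project the centerline and its tangents orthogonally into
the chosen plane, renormalize, keep tangents oriented rostral→caudal,
and report the maximum pairwise angle in [0, 180°) (ties broken by the
lexicographically smallest parameter pair).  For a planar circular arc
this equals the subtended angle; for an S-shaped spine whose tangent
swings between −α and +α it accumulates both lobes (2α).  Agreement
with manual endplate-based measurements is approximate by construction.
Grid points whose projected tangent nearly vanishes are dropped; if
more than half vanish, the curve is essentially orthogonal to the plane
and the projection is refused.

## Permutation test

Two groups of per-spine scalar summaries are compared by
T = stat(A) − stat(B) (mean difference by default; median difference
available).  The null re-assigns the pooled values to groups of the
original sizes: exhaustively when the number of assignments is ≤
20,000 — which covers the 5-vs-5 design (252) exactly — with
p = #{T* as-or-more-extreme}/N (inclusive ≥, so the observed assignment
counts); otherwise seeded Monte-Carlo with p = (1 + #extreme)/(B + 1),
never zero.  Two-sided tests use |T*| ≥ |T|.  The exhaustive p-value is
discrete (multiples of 1/252 at n = 5 + 5) and slightly conservative at
fixed α; the measured null rejection rate at α = 0.05 is ≈ 0.048 and
the power at a 3-pooled-SD shift of the summary is ≈ 0.98.

## Synthetic spines

The generator emulates annotated micro-CT spines: an analytic planar
centerline sampled at n equally spaced arc-length stations (default 24
vertebrae over 80 mm), a ring of 8 landmarks of radius 0.8 mm in the
plane normal to the local tangent at each station, isotropic Gaussian
landmark noise, and a per-spine RNG stream derived deterministically
from (seed, group, index).  Shapes: straight; circular arc subtending
the amplitude (validated ≤ 180° against self-intersection; Cobb =
amplitude; kappa = amplitude/length); an S-curve whose tangent angle
swings sinusoidally between ±amplitude about the long axis (two opposed
lobes, Cobb = 2 × amplitude — note that a literal chain of two opposed
α-arcs would have tangent range α, not 2α, so the anti-symmetric swing
is the construction that matches the "sum of opposed lobes" reading of
an S deformity); and a displacement sinusoid (amplitude in mm,
`n_periods` periods, numerically re-parametrized to arc length).
Population generation draws per-mouse amplitudes from
Normal(template amplitude, between-mouse SD), truncated at zero by
clipping.  `study_like_templates()` encodes the reported two-genotype
contrast (2.4 ± 0.9° vs 19.3 ± 9.4°, coronal arc, n = 5 per group) that
the demo and the acceptance script re-simulate.

Ground truth (centerline, tangents, curvature, Cobb) is emitted next
to every generated cloud, so recovery tests never re-derive it.

What the generator does *not* emulate: vertebral shape and pose (rings
are ideal circles), non-planar deformities, segmentation/landmarking
systematics, or inter-vertebra spacing irregularities.  Passing
recovery tests therefore establishes correctness of the estimators
under the stated noise model, not robustness to annotation artefacts.

## Differential-proteome filter

A record is retained iff n_peptides ≥ 2 AND q ≤ 0.05 AND log₂FC
outside (−0.321, 0.263); all comparisons inclusive.  The band is kept
asymmetric exactly as printed (−0.321 = log₂ 0.8, 0.263 = log₂ 1.2,
i.e. ≥ 20% change in either direction on the linear scale) rather than
symmetrized.  Exclusion reasons record the first failing criterion in
the order peptides → q → band.  The packaged 38-row dHT-vs-WT table
stores the published linear fold changes and q-values; peptide counts
are not part of the published list, so the fixture sets n_peptides = 2
(every listed protein passed the ≥2-peptide cut by construction).  The
upstream moderated-t/Benjamini–Hochberg machinery that produces
q-values is out of scope.

## Calcium transients

F_rest is the mean of all pre-stimulus samples; F_max the maximum
post-stimulus sample; ΔF/F₀ = (F_max − F_rest)/F_rest.  TTP is the
time from stimulus to the peak sample; HTTP the time from stimulus to
the first crossing of F_rest + 0.5(F_max − F_rest) on the rising
phase, by linear interpolation between samples; HRT the time from the
peak to the first crossing of the same level on the falling phase,
also interpolated.  A trace that never relaxes to half amplitude gets
HRT = None.  No smoothing precedes peak detection by default; an
optional 3-point median filter handles spike artefacts.

The synthetic transient is
F(t) = F_rest + A·(e^(−(t−t₀)/τd) − e^(−(t−t₀)/τr))/s_norm for
t ≥ t₀, with s_norm scaling the bracket so the analytic peak equals A
exactly (peak time t* = ln(τd/τr)·τrτd/(τd − τr)); defaults
(F_rest = 1000 a.u., A = 1310, τr = 3 ms, τd = 25 ms, 300 frames/s)
give a wild-type-like ΔF/F₀ of 1.31.  Because the trace is sampled at
discrete frames, exact amplitude recovery requires a frame to coincide
with t*; the synthetic protocol therefore places the stimulus at
t₀ = k/300 − t* so the analytic peak lands on a frame.  With arbitrary
stimulus placement the sampled peak underestimates A by up to
~f″(t*)/2·(Δt/2)² (≈ 2% at the default time constants), which is a
property of 300 Hz sampling, not of the estimator.

## Numerical choices and degenerate inputs

Curvature below 1e-12 mm⁻¹ is flat (r = +inf); tangent norms below
1e-12 raise a degenerate-tangent error; duplicate consecutive
centroids break chord-length parametrization and are rejected; fits
need ≥ 4 points; Cobb needs ≥ 3 projected tangent samples; projected
tangent norms below 1e-9 are dropped.  Monte-Carlo permutation needs
≥ 100 permutations.  Trace readers require strictly increasing time
with ≤ 1% sampling jitter and infer the rate from the median step.
Intensities are clipped at zero in the generator to keep traces
physical.

## Problem sizes

The default analyses are desk-scale: 24-vertebra spines on a 512-point
grid, 252-assignment exhaustive permutation tests, 2000 null and 500
power simulations for calibration, and 40 replicate 5-vs-5 cohorts for
the group-contrast summary.  These sizes give Monte-Carlo standard
errors comfortably inside the tolerances quoted above.

## Known limitations

* The analytic Cobb surrogate is not the clinical endplate measurement;
  agreement on real vertebrae is approximate.
* The flat-end constraint trades end-region fidelity for interior
  stability; max-kappa summaries inherit a bounded end-transition
  overshoot when true end curvature is nonzero.
* The permutation test assumes exchangeability of mice under the null;
  covariates (weight, sex) are not modelled.
* Kinetic definitions (TTP from stimulus, interpolated half-crossings,
  rest = pre-stimulus mean) are fixed as this module's contract;
  recordings analysed under other conventions may differ by up to one
  frame interval.
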