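# spinemetry

Quantitative analyses for mouse models that link recessive *Ryr1*
mutations to muscle-spindle dysfunction and skeletal deformity:

* **3-D spine morphometry** — a parametric cubic-spline centerline
  γ(t) = (γx(t), γy(t), γz(t)), t ∈ [0, 1], fitted to vertebral landmark
  centroids and constrained to be *flat* (zero curvature) at its
  extremes; curvature κ(t) = ‖γ′ × γ″‖ / ‖γ′‖³ and radius r(t) = 1/κ(t)
  profiles with arc-length-weighted summaries.
* **Analytic Cobb angle** — the maximum angle between rostral→caudal
  oriented centerline tangents after projection into the coronal
  (scoliosis) or sagittal (kyphosis) plane; for a planar circular arc it
  equals the subtended angle.
* **Two-sample permutation test** — compares populations of spines via
  per-spine curvature summaries; exhaustive enumeration for small
  designs (C(10,5) = 252 for the usual 5-vs-5 comparison), seeded
  Monte-Carlo with add-one correction otherwise.
* **Differential-proteome filter** — the retention rule for protein
  quantification tables: ≥ 2 peptides, q ≤ 0.05 and log₂ fold change
  outside [−0.321, 0.263] (a ±20% change on the linear scale); retained
  proteins are split into up- and down-regulated sets. A published
  38-protein dHT-vs-WT intrafusal table ships as a packaged TSV.
* **Calcium-transient kinetics** — ΔF/F₀ = (F_max − F_rest)/F_rest,
  time to peak (TTP), half time to peak (HTTP) and half relaxation time
  (HRT) of electrically evoked transients sampled at 300 frames/s.
* **Synthetic-data generators** — seeded landmark clouds (24 vertebrae
  × 8 landmarks on rings around analytic centerlines), two-group
  populations with between-mouse amplitude spread, and
  double-exponential fluorescence transients — every generator emits
  its analytic ground truth next to the data.

Intended users: researchers quantifying scoliosis/kyphosis from
micro-CT landmark annotations, analysing muscle-spindle proteomics or
intrafusal calcium imaging, and anyone needing a tested, reproducible
reference implementation of these measurements.

## Worked example

The `demo` subcommand simulates a wild-type-like and a mutant-like
group of five spines each (coronal arc deformities drawn from
2.4 ± 0.9° and 19.3 ± 9.4°, 0.1 mm landmark noise), fits every spine,
and compares the groups:

```sh
$ spinemetry demo --seed 1 --out demo_out
spine_id group  cobb_deg  mean_kappa_per_mm  total_curvature_rad
   WT-00    WT  2.779035           0.000683             0.054700
   WT-01    WT  2.282281           0.000826             0.066069
   WT-02    WT  3.032410           0.000720             0.057607
   WT-03    WT  2.795127           0.000826             0.066063
   WT-04    WT  1.927125           0.000579             0.046305
  dHT-00   dHT 23.950462           0.005238             0.419087
  dHT-01   dHT 22.941611           0.005017             0.401364
  dHT-02   dHT 15.463977           0.003382             0.270727
  dHT-03   dHT 28.294125           0.006197             0.495229
  dHT-04   dHT  4.102620           0.000954             0.076371
group mean Cobb (deg): WT=2.56 dHT=18.95
permutation test (mean curvature, exhaustive): p=0.007937
```

Each row is one simulated mouse: its coronal Cobb angle in degrees, its
arc-length-weighted mean curvature (mm⁻¹) and its total curvature
(radians; for a planar curve, the total turning of the tangent).  The
group means recover the generating 2.4°/19.3° contrast, and the
exhaustive permutation test on mean curvature rejects the null at
p = 2/252.  The output directory contains the landmarks CSV, per-spine
results, the permutation result with the embedded run configuration,
and a manifest recording the command line, seed and input digests.

Other subcommands: `simulate`, `curvature`, `cobb`, `permtest`,
`catrace`, `dediff` — see `spinemetry <cmd> --help`.  Library use
mirrors the CLI:

```python
import spinemetry as sm

cloud, truth = sm.generate_spine(
    sm.SpineTemplate(shape="arc", deformity_amplitude=35.0, noise_sd=0.0))
curve = sm.fit_spine_curve(sm.collapse_vertebrae(cloud))
angle = sm.cobb_angle(sm.project_curve(curve, "coronal")).angle_deg
# angle == 34.89, truth.cobb_deg == 35.0
```

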