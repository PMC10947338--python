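# Methods

## Problem and scope

`dosepred3d` predicts the 3D dose distribution of a single-target female
pelvis VMAT plan (45 Gy in 25 fractions) from the patient's CT and structure
set, and uses the prediction for plan quality assurance: comparing a
clinical ("reference") dose against the model's estimate of what is
achievable, testing equivalence, flagging plans where the prediction
indicates meaningful OAR sparing, and extracting replanning objectives.
Clinical DICOM ingestion, treatment-planning-system re-optimization, and
deliverability modeling are out of scope; dose grids are the unit of
exchange.

## Synthetic cohort

Because the package must be testable without clinical data, it ships a
first-class phantom generator rather than fixtures.

**Anatomy.** Each phantom is a set of ellipsoids on a regular grid
(default 64³ voxels at 3 mm; a geometric scaling helper fits the same layout
to smaller grids such as 48³). The body is a large ellipsoid; the PTV sits
centrally; bladder (anterior-inferior), rectum (posterior), bowel bag
(superior-anterior), femoral heads, kidneys, liver, spinal cord and four
bony structures are placed at anatomically sensible offsets. Per-plan
variation comes from seeded Gaussian jitter of every organ's center
(σ = 3 mm) and radii (σ = 5%, clipped to ±15%); all organ masks are
intersected with the body so nesting holds by construction. CT intensities
are painted per organ in Hounsfield units (soft tissue ≈ 40 HU, bone
≈ 600–700 HU, air −1000 HU) with σ = 15 HU Gaussian noise, then normalized.

**Dose.** The reference dose is analytic so every point value and DVH
statistic has a closed form:

* inside the PTV: `Rx · (1 + h·g(x))` with `g` a seeded Gaussian bump in
  (0, 1] — dose lies in `[Rx, (1+h)·Rx]`; the hotspot fraction default is
  h = 0.05, consistent with a ~105% in-target hotspot being the edge of
  clinical acceptability;
* outside: `Rx · exp(−d/τ) · s(x)`, `d` the Euclidean distance (mm) to the
  PTV surface (exact distance transform with physical spacing) and `s(x)` a
  piecewise-constant sparing factor: the factor of the nearest spared OAR
  wherever that OAR is within 25 mm, 1 elsewhere. Sparing factors (0.5 for
  spinal cord up to 0.9 for bowel bag) create the directional structure a
  VMAT optimizer produces;
* zero outside the body.

The falloff length τ = 15 mm makes the dose fall to half ~10 mm from the
PTV edge, a realistic VMAT gradient. These defaults are study conditions,
fixed once; they are not fitted to any test.

**What the phantom does not emulate:** multi-arc fluence structure,
heterogeneity effects, couch/immobilization devices, inter-planner
variability, and multi-dose-level targets. Passing tests therefore
demonstrate that the machinery (representation, loss, training, inference,
metrics) works end to end on data with the right statistical shape — not
clinical-grade accuracy on real plans.

**Split.** Cohorts are split 3:1:1 by largest-remainder allocation — the
only rounding convention that yields 47/16/16 from 79 plans — with a seeded
shuffle.

## Input representation

Sixteen channels in a fixed order: normalized CT, target array
(prescription dose in Gy on PTV voxels, zero elsewhere), then body and 13
structure masks. The L4 and L5 vertebral bodies are separate channels.
CT normalization is `(clip(HU, −1000, 1000) + 1000)/2000`. Resampling
uses trilinear interpolation for continuous volumes and nearest-neighbour
for masks (preserving binarity), with a node-centered convention
(`world = origin + index·spacing`). A structure missing from an input set
becomes an all-zero channel with a logged warning, since real structure
sets are routinely incomplete.

## Network and training

The architecture is an encoder–decoder with dense blocks (each convolution
sees the concatenation of the block input and all previous features) and a
dilated bottleneck; the output head is a 1×1×1 convolution with softplus,
so predicted dose is non-negative by construction. The implementation is
pure numpy with hand-written backpropagation (im2col convolutions, manual
adjoints) and Adam — compact and fully deterministic on CPU, sized for the
desk-scale studies this package targets. The default configuration is
3 levels / 4-layer blocks / growth 16 / bottleneck dilations {1, 2, 4}; the
scaled studies use 1 level / 1-layer blocks / growth 8 / dilations {1, 2}
(≈ 26k parameters). The receptive field is computed and exposed at build
time.

**Loss.** `MSE + λ·Σ_V |ΔD_V%|` with λ = 0.25 and V ∈ {1, 95, 98}. `D_V%`
is computed by exact sorting (the `ceil(V·N/100)`-th largest masked voxel),
and its subgradient is routed to the voxel realizing the order statistic;
a patch containing no PTV voxel contributes MSE only, which keeps every
random patch usable. The absolute value follows the method's definition of
the DVH terms as absolute errors.

**Schedule.** Adam at 0.001; the learning rate is halved after every 55
consecutive epochs without a strictly lower validation loss; training stops
early after a configurable patience (default 150) and never exceeds 1000
epochs; the returned weights are those with the best validation loss.
Validation may be evaluated on a central crop (`val_patch_size`) to bound
per-epoch cost; the scaled studies validate on 32³ centers.

**Inference.** Overlapping patches with stride 16 per axis, the final
offset clamped to the boundary (no padding, so no fabricated out-of-body
context); every voxel's prediction is the arithmetic mean over all
(model, covering patch) values — plain averaging, no Gaussian window. The
ensemble default is three members differing only in seed. The averaged
volume is renormalized once — `D_norm = D_pred · D95_ref / D95_pred` on the
PTV — which makes the predicted D95 match the reference exactly (to float
tolerance) and anchors all downstream coverage metrics.

## Plan evaluation

* **DVH**: cumulative, fraction of structure volume receiving at least each
  edge; default bin width 0.1 Gy. Percentile metrics are computed from the
  exact sort, not the binned curve, so they agree with brute-force oracles
  to the bit.
* **CI** = (PTV voxels ≥ level)/(all voxels ≥ level) at 95% of the
  prescription (42.75 Gy); voxel counting, no partial-volume weighting. An
  empty isodose volume raises rather than yielding 0/0.
* **HI** = D5%/D95% (≥ 1 by percentile monotonicity).
* **Deltas**: PTV `ΔD_V%` as relative percentages; OAR `ΔDmean`/`ΔDmax` in
  Gy with `Dmax` the single hottest voxel; the voxel-wise mean difference is
  averaged inside the body mask (a whole-grid mean would be dominated by
  air).
* **TOST**: paired two one-sided t-tests at a 1 Gy bound, α = 0.05,
  equivalent iff both one-sided tests reject (`max(p_lower, p_upper) < α`);
  backed by `statsmodels.ttost_paired`. A zero-variance difference vector
  (undefined t) is judged by `|mean| < bound` directly. The report applies
  it to per-plan body mean doses; the function accepts any paired vector.
* **Flagging**: a plan is flagged when any OAR's prediction spares at least
  θ_mean = 2 Gy in mean dose or θ_max = 3 Gy in max dose (configurable;
  the thresholds are a conservative operating point for an otherwise
  qualitative selection). Flagged OARs get max-dose and max-DVH point
  objectives at the predicted values, optionally scaled by a push factor
  ≤ 1; dose-falloff planning structures are `body − isodose(pred, L)` for
  L ∈ {40, 20} Gy with max-dose objectives at L.

## Scaled study conditions

Tests and the acceptance script run the method end to end at desk scale,
chosen once: 54 phantoms at 48³ / 3 mm (largest-remainder 3:1:1 →
32/11/11, so the training partition holds 32 plans), the compact network
above, 24³ training patches, 48 patches per epoch in batches of 4,
inference patches 24³ at stride 16. The single-model accuracy study trains
up to 20 epochs; three-member ensemble runs train 10 epochs per member. On
one CPU this trains in a few minutes per model and reaches a held-out mean
absolute voxel error of a few percent of the prescription inside the body.

## Numerical notes and limitations

* All randomness flows from explicit integer seeds (`numpy` Generators);
  per-plan seeds derive from the cohort seed via `SeedSequence` spawning.
  CPU numpy arithmetic makes identical runs bit-identical.
* Dose volumes are float32; loss and metric accumulation is float64.
* The DVH loss is piecewise differentiable; at ties the subgradient picks
  the stably-sorted voxel.
* The analytic dose is discontinuous at the PTV surface (by design — the
  in-target plateau meets the falloff at `Rx`); networks smooth this edge,
  which is the main residual error source near the target boundary.
* The numpy engine has no GPU path and no stochastic augmentation; training
  at clinical scale (64³ patches, hundreds of epochs, full-resolution
  grids) is outside its intended envelope.
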