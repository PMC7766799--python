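# Methods

This note documents the models, conventions and numerical choices
behind `leadtract`, and what the synthetic cohort does and does not
establish about real data.

## Coordinate and volume conventions

World space is scanner/patient millimetre space as given by the NIfTI
affine (RAS assumed); no template normalization is performed — the
analysis is meant to run in individual patient space.  Voxel indices
are 0-based and a voxel's world position is its centre.  The voxel
volume is |det| of the 3×3 affine block, so it is exact for rotated
and anisotropic grids (e.g. a 0.49 × 0.49 × 1.0 mm structural grid
gives 0.2401 mm³).  Resampling (nearest or trilinear, via
`scipy.ndimage.map_coordinates`) fills 0 outside the source extent:
tract probability outside the mapped field is treated as no tract.
Masks are written as unsigned 8-bit, probability and field maps as
32-bit float.

## Lead geometry

The directional lead is modelled as a cylinder of radius 0.65 mm with
four contact levels (1-3-3-1): level axial centres sit at
`tip_to_first_contact + contact_length/2 + (level−1)(contact_length +
gap)` along the shaft, with 1.5 mm contacts and 0.5 mm gaps by
default.  These dimensions are manufacturer-derived defaults for the
modelled hardware and are fully configurable in `LeadSpec`.  Segments
within a level are spaced 120° apart; rotation 0° points the reference
segment anterior (+y), applied by Rodrigues rotation about the shaft
axis.  Contacts are numbered 1 (ventral ring) to 8 (dorsal ring).

For the field model each contact is discretized into `n_subsources`
weighted points.  With `n = 1` (the default) the source sits at the
contact's analytic centroid — on the axis for a ring, at radial
distance `r·sin(α/2)/(α/2)` for a segment of arc α.  The single-point
default is justified by scale separation: at 2 mA the activation
radius (≈ 2.8 mm) is large against the contact dimensions
(≤ 1.5 mm), so source-distribution detail perturbs the VTA boundary
by well under a voxel.  Larger `n` tiles the contact surface with
stratified angles and golden-ratio heights (quasi-uniform, so the
discrete centroid converges to the analytic one).

## Field model and VTA

The field is an analytic point-source superposition in an infinite
homogeneous isotropic medium: field *vectors* `(I w_k /4πσ) Δ_k/|Δ_k|³`
are summed over sub-sources before taking the magnitude.  With I in
mA, σ in S/m and distances in mm the expression evaluates directly in
V/mm.  This is a deliberate model choice in place of precomputed
finite-element field libraries: it is transparent, dependency-free and
exactly checkable against closed forms, while honouring the same
contract (σ = 0.1 S/m, threshold 0.2 V/mm, 2 mA).  No fidelity to any
particular FEM implementation is claimed; heterogeneous or anisotropic
conductivity and axon-cable activation models are out of scope.  Pulse
width and frequency are metadata only — the analysis runs at a single
fixed setting, so no pulse-width threshold rescaling is applied.

A voxel belongs to the VTA iff the field magnitude at its centre
reaches the threshold (no partial-volume weighting).  Evaluation
points closer than half a voxel to a source are clamped to that guard
radius with a warning (the field diverges at the source).  The VTA is
rasterized directly on the tract map's grid, avoiding a resampling
step whose voxel-size change would alter overlap values.
Discretization error: for a 2 mm grid the surface-shell bound
(sphere area × voxel diagonal) is loose; the acceptance check on a
0.2 mm grid reproduces the analytic 94.0 mm³ sphere to < 0.1%.

## Overlap score

`score = Σ_{v∈VTA} p(v) × voxel_volume` (mm³).  Probability maps come
from streamline visitation counts divided by the total number of
streamline samples retained by the tracking run (the "waytotal"
convention); the normalizer is explicit and configurable because
published conventions differ by a per-voxel rescaling — any such
monotone rescaling changes absolute mm³ values but not contact ranks.
Scoring refuses mismatched grids rather than silently resampling.  The
top-decile display threshold is visualization-only; scoring always
uses the full map.

## Ranking and concordance

Within a hemisphere contacts are competition-ranked by overlap (ties
share the better rank; the next rank is skipped).  The best-clinical
set contains every contact attaining the maximum improvement —
with coarse integer tremor scores, exact ties are common and all tied
contacts count.  A top-k hit means some contact with overlap rank ≤ k
is in that set; a tie at rank k counts all tied contacts.  The
directional-only analysis restricts both the ranking and the
best-clinical set to contacts 2–7 before evaluation, and the
tie-inclusive hit rule is applied uniformly there too.  Rates are
reported to one decimal; uniform chance among six directional
candidates is 16.7%.

## Clinical scoring

Postural, intention and rest tremor are integers 0–4 (half-points
rejected); improvement is the percent change of their sum vs the OFF
baseline, positive = reduction.  Hemispheres with a zero OFF baseline
are excluded with a logged warning rather than assigned 0% — with no
tremor to suppress the quantity is undefined.

## Mixed-effects model

`improvement ~ 1 + overlap` with a random intercept per lead
(patient × hemisphere), REML via `statsmodels.MixedLM`; the slope
p-value is a Wald test.  Random-intercept-only is the default (the
repeated-testing design shifts a lead's level, not its slope); random
slopes are available via `random_slope=True`.  Overlap enters on its
raw mm³ scale.  Variance explained follows the Nakagawa–Schielzeth
decomposition with σ²_fixed the population (1/n) variance of the
fixed-effect predictions; marginal ≤ conditional holds by
construction.  Two numerical guards: data lying exactly on a line
(zero residual variance) are resolved by the closed-form fit rather
than the iterative optimizer, and boundary fits (random variance → 0)
that make the gradient-based optimizer's matrices singular fall back
to derivative-free Powell optimization with zero best-linear-unbiased
predictions.

## Synthetic cohort

The generator defines the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| patients / leads | 7 / 14 | bilateral cohort at clinical scale |
| grid | 41³ voxels, 2.0 mm iso | diffusion-space voxel size; odd extent puts the midline on a voxel-centre plane |
| tract | Gaussian tube, radius 2.5 mm | closed-form voxel values; falloff scale of a thin fibre bundle on a 2 mm grid |
| lead displacement | uniform 0–6 mm ⟂ shaft | spans on-tract to clearly-off-tract placements |
| response | β₀ = 5%, β₁ = 0.8 %/mm³, σ_lead = 10%, σ_resid = 8% | maps the realized overlap range (≈4–80 mm³) into a non-saturating 10–70% improvement band with visible lead-to-lead heterogeneity |
| baseline TRS | (3, 3, 2) = 8 | moderate baseline tremor; 12.5% improvement granularity |

The tube is mirrored across x = 0 for the left hemisphere; lead shafts
run parallel to the tract chord with seeded uniform perpendicular
displacement, azimuth and rotation.  Latent improvements are clipped
at 100% and discretized through integer TRS tables (ON sum =
round(baseline·(1 − latent/100)) clamped to 0–12), so observed
improvements live on the baseline's granularity lattice — this is what
produces the clinically realistic equal-best ties.  The observed value
never deviates from the clipped latent one by more than half a
baseline unit.

What the synthetic cohort does *not* emulate: anatomically realistic
tract trajectories and curvature, spatially varying tract probability
within the cross-section, lead trajectories oblique to the tract,
side-effect limits on usable contacts, and measurement structure
beyond additive Gaussian lead/residual noise.  Passing tests therefore
establish the correctness of the computational pipeline and the
statistical machinery under its own assumptions, not clinical
predictive performance.

## Problem sizes

Unit tests run on 5–20-voxel fixtures; analytic field checks use a
35³ grid at 0.2 mm; the end-to-end runs use the 14-lead default
cohort (112 VTA/overlap computations on the 41³ grid, a few seconds);
parameter recovery uses 200 replicates of 50 leads × 8 contacts,
fitting each with REML (~20 s total).

## Known limitations

* The field model ignores the insulating lead body and tissue
  heterogeneity; absolute VTA sizes inherit the point-source
  idealization.
* All contacts are assumed to source the full programmed current;
  no reduced effective current density for segments.
* Overlap mm³ values depend on the probability-map normalization
  convention; only ranks are convention-invariant.
* The mixed model assumes Gaussian errors on a percent scale that is
  bounded above and ties are induced by discretization; with heavy
  clipping at 100% the linear model misspecifies the tail.
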