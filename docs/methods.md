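# Methods

## Kinetic model

Tissue enhancement follows a one-compartment realization of the simplified
Johnson-Wilson description with three free parameters (MBF, arterial delay,
decay constant):

C_t(t) = (MBF/6000) · ∫₀ᵗ C_a(τ − d) e^{−k(t−τ)} dτ,

MBF in mL·min⁻¹·(100 g)⁻¹ throughout (factor 1/6000 converts to s⁻¹ assuming
1 g/mL tissue). The published description of the underlying estimator does
not print its equation; this convolution form is the package's adopted
realization and all claims about it are validated against the package's own
forward model. The integral is evaluated by trapezoidal quadrature with the
exponential factored into a numerically stable rescaled cumulative sum; the
delay shifts the sampled AIF by linear interpolation (zero before
acquisition, no extrapolation past the window).

Fitting (`fit_rpm1` / `Rpm1Fitter`): the model is linear in MBF for fixed
(delay, k), so the fitter evaluates a coarse grid — delay every 0.5 s over
[0, 10] s, 16 log-spaced k values over [0.005, 1] s⁻¹ plus k = 0 — with the
closed-form least-squares MBF (clipped to [0, 600]) at each node, then
refines (delay, k) from the best node with Nelder-Mead, MBF still closed
form. The returned residual never exceeds the best grid node's (accept rule),
which gives the oracle-dominance property checked in the tests. Bounds are a
generous physiologic envelope and configurable.

Identifiability: within a 30 s acquisition window the washout constant and
MBF trade off; single-voxel fits at 15–20 HU noise scatter by tens of
mL·min⁻¹·(100 g)⁻¹ around truth with a small positive median bias (the MBF
floor at zero truncates the lower tail). This is why the map stage pools
voxels before fitting.

## SLICR map stage

Myocardial voxels are clustered by SLIC (scikit-image implementation) on
features [voxel position, TAC normalized to unit global peak], anisotropic
voxel spacing respected, compactness 0.2, target cluster size 25 voxels,
≤10 iterations. Clusters are post-processed to be 26-connected; fragments
under 3 voxels merge into the contacting cluster with the largest shared
boundary. Each cluster's **median** TAC is fitted and the fitted MBF
broadcast to member voxels; non-converged clusters are flagged in the output
table, never dropped silently. A per-voxel fitting mode exists as the
comparison baseline; on a 20 HU-noise uniform phantom SLICR reduces map RMSE
roughly five-fold. SLIC's spatial term can misplace a handful of voxels at a
sharp perfusion-sector boundary; the median TAC absorbs them, so cluster
values still separate deficit from remote tissue cleanly.

## Beam-hardening correction (ABHC)

The artifact model is a cupping-style radial polynomial scaled by the
instantaneous blood-pool iodine enhancement: bias(ρ, t) = E(t)·Σᵢ cᵢ ρⁱ
(i = 1..3, no constant term), where ρ is in-plane radius from the LV-pool
centroid normalized to the outer myocardial boundary, applied for ρ ≤ 1.25.
E(t) is the mean LV+aorta enhancement above its pre-contrast baseline. The
same family generates the phantom's artifact and defines the correction — a
deliberate simulation-matched simplification (the upstream method's exact
cost terms are not published), not a claim about scanner physics.

The correction minimizes, by Nelder-Mead from the zero (identity) vector, the
cost: mean over frames of within-myocardium HU variance **plus
within-LV-pool variance**, plus λ (default 1) times the mean squared
frame-to-frame change of the myocardial mean over negligible-enhancement
frames (< 2% of peak). The LV-pool term is required for identifiability: the
myocardial annulus spans too narrow a radial range to pin the polynomial, and
the unconstrained component is a per-frame offset proportional to E(t) that
would corrupt tissue curves (and hence MBF) while leaving the
myocardium-only variance unchanged. Masks are eroded one voxel in-plane
before the cost is computed so partial-volume rims from imperfect
segmentation are not "corrected" as if they were artifact. If the optimizer
fails to beat the identity cost, the identity is returned with a
`converged=False` flag — the corrected cost never exceeds the uncorrected
one. With noise, the cost has an irreducible noise-variance floor, so
fractional cost reduction is only meaningful on low-noise data; the MBF
improvement is demonstrated under noise separately.

## Preprocessing

- **Aorta ROI**: voxels ranked by temporal enhancement range, thresholded at
  50% of the maximum, connected components scored by mean per-slice
  circularity (4πA/P²); among circular candidates the smallest cross-section
  wins (in short-axis sections the ascending aorta is smaller than the LV
  pool). The component is eroded one in-plane voxel before the mean TAC is
  taken (boundary voxels are diluted by partial volume and motion). The TAC
  baseline is the mean over frames strictly before the first exceeding 5% of
  the enhancement range.
- **Registration**: per-frame 3-D translation to the peak-enhancement frame
  by phase correlation (10× upsampling, plain cross-correlation), frames
  edge-padded by 25% per axis beforehand — FFT correlation is circular, and
  without padding shifts comparable to a short stack's extent alias.
  Translations are recovered to ≈0.1 voxel when relative motion stays below
  about a quarter of the z coverage; purely z-uniform objects are a
  degenerate case (nothing to register on), which is why the phantom tapers.
- **Segmentation**: external label volumes pass through after geometry
  validation (the integration point for any trained model). The classical
  fallback thresholds the peak-enhancement frame (Otsu split of foreground
  into blood vs tissue; blood components split into LV pool = largest and
  aorta = most circular; myocardium = mid-intensity band connected to the LV
  within a 16 mm ring), with in-plane Gaussian smoothing applied only when
  the estimated noise exceeds 5 HU.
- **Landmarks**: LV center from the blood-pool centroid over mid slices.
  Septal insertion points from the angular extremes of an RV blood structure
  abutting the myocardium; without an RV the anterior insertion angle must be
  supplied (the inferior defaults to 120° clockwise). The anterior insertion
  fixes the polar-map angle origin.
- **Reorientation**: trilinear world-space resampling rotating the LV long
  axis onto z; label volumes use nearest neighbour; exact identity when
  already aligned.

## Polar map and AHA-16 report

Each short-axis slice maps linearly to a radial band of the bullseye (apex at
the center); myocardial voxels are binned by angle about the LV center
measured counterclockwise (viewed from the apex) from the anterior RV
insertion; samples within a bin average. Default raster 24 × 72
(angles must be multiples of 24 bins so the 60° and 90° segment boundaries
fall on bin edges). Segments: basal 1–6 and mid 7–12 at 60° each, apical
13–16 at 90° with centers aligned to the corresponding basal/mid anatomical
directions (boundaries offset 45°) — the standard display geometry. The
apical cap (segment 17) is not modelled. A segment is excluded when fewer
than 30% of its raster bins are sampled; "segment area" means all raster bins
geometrically in the segment. Segment means are computed on the raster (the
exclusion rule is raster-native); the global mean is the mean over included
segment means.

Territory adjacency is generated from geometry: same ring and angularly
touching, or adjacent rings and angularly overlapping/touching; rings two
apart are never adjacent. Under the stated geometry this reproduces the
canonical 10-pair LAD list exactly (shipped with a regeneration test); RCA
and LCX get 8 pairs each. Representative territory MBF = minimum pair mean
over adjacent included pairs (ties to the first/lowest pair); relative MBF
normalizes segment means to the territory with the highest representative
value. Ischemia uses strict `<` at the threshold: a territory exactly at the
cutoff is not ischemic. Right-dominant assignment is fixed
(LAD {1,2,7,8,13,14}, RCA {3,4,9,10,15}, LCX {5,6,11,12,16}).

## Cohort statistics and classification

CAD-RADS bins integer percent stenosis as {0}, 1–24, 25–49, 50–69, 70–99,
{100} → grades 0–5 (non-integer reads truncate toward zero); grade ≥ 3 is
obstructive. Threshold derivation restricts to unequivocal territories
(grades 0 and 4; grade 4 is the positive class, called positive when
MBF < t), enumerates candidate thresholds at midpoints of sorted unique MBF
values, maximizes Youden's J with ties to the lowest threshold, and reports
the mean over 1,000 bootstrap replicates with a percentile 2.5–97.5 CI.
Replicates resample rows, or patients with all their territories when
stratified; single-class replicates are redrawn. Spearman correlation is
mid-rank with the t-approximation p-value, and the group test is the
pooled-variance two-sided t-test (both via scipy, with degenerate-input
conventions documented in the API).

Classification rules are evaluated in order: (1) any obstructive territory
with MBF below threshold → `flow_limiting`; (2) no obstructive vessel and
diffuse ischemia (>50% of included AHA segments ischemic AND global mean
below threshold; per-territory proxy when no report is available) →
`mvd_diffuse`; (3) no obstructive vessel, ≥1 ischemic territory →
`mvd_focal`; (4) obstructive but all territories preserved →
`discordant_preserved`; (5) `normal`. Flow-limiting precedence over MVD when
both patterns coexist is this package's choice and is configurable in
spirit — a diabetic with obstructive disease classifies by the stenosis
first.

## Synthetic data

The phantom is a short-axis LV: concentric blood-pool/myocardium cylinders
tapering 25% toward the apex (slice 0), embedded with background margins
above and below, plus a full-length aortic cylinder and an optional RV stub
for landmark work. Blood voxels carry a gamma-variate AIF (peak 350 HU at
onset + αβ = 10 s, 10% recirculation bump delayed 12 s — a standard surrogate
for a measured aortic input); each myocardial voxel's curve comes from the
forward model with its angular/slice sector's truth parameters (default
uniform 300 mL·min⁻¹·(100 g)⁻¹, delay 2 s, k 0.15 s⁻¹ — normal stress flow).
Defaults: 64×64×12 voxels at 2×2×4 mm, 31 frames at 1 s (a 30 s stress
acquisition), baselines 45 HU (tissue and blood) over −80 HU background,
i.i.d. Gaussian noise 15 HU, ±1 voxel integer frame translations; cupping
and the RV stub are off unless configured. The taper exists for realism and
because a z-uniform cylinder makes z registration ill-posed. The full truth
payload (masks, per-voxel parameter maps, AIF, shifts, artifact coefficients)
travels with the study, and identical seeds give bit-identical studies.

The phantom does **not** emulate: projection-domain physics (the artifact is
the image-domain family above), correlated or non-Gaussian noise, cardiac
deformation or rotation (motion is translational), partial-volume blur at
tissue interfaces beyond voxelization, anatomy beyond cylinders, or
ECG-gating effects. Tests passing on it demonstrate correctness of the
estimation and reporting machinery under controlled conditions, not clinical
performance.

The cohort generator draws one row per (patient, vessel): CAD-RADS from a
per-vessel distribution chosen so ~17% of vessels are obstructive (matching
the reported patient-level counts), territory MBF from N(274, 62) without
obstruction and N(165, 61) with (the reported non-diabetic per-vessel group
statistics), and for patients carrying the MVD process (diabetics, 80%
probability; prevalence 18/104, female fraction 41/104) every territory from
N(130, 35) — a diffuse, tight, low distribution with global mean well below
the 200 cutoff, as reported polar-map distributions show. The retained
`is_mvd` truth label marks *identifiable* MVD — the MVD process in a patient
with no obstructive vessel — matching the operational clinical definition
(low flow with CAD-RADS < 3); an MVD-process patient with coexisting
obstructive disease is truthfully labelled non-MVD because the
stenosis-first precedence rule will (correctly) classify them as
flow-limiting. MVD recovery in `cohort_summary` scores the `mvd_diffuse`
prediction: under N(274, 62) territories a normal patient shows an isolated
sub-200 territory ~11% of the time, so counting focal calls as MVD would cap
specificity near 0.7; the diffuse pattern is the disease signature.

## Numerical and testing choices

Problem sizes: the acceptance run uses a 336-point zero-noise recovery
lattice, 2,000 noisy fits (200 × 10 seeds), ~250-voxel phantoms for paired
SLICR/voxelwise comparisons, 1,000 random reports for the pair-minimum
oracle, 500+500 rows × 1,000 bootstrap replicates for threshold recovery, and
a 400-patient cohort for classification recovery — sizes at which every
stochastic check is stable across seeds. Degenerate inputs raise typed
errors (`InputError`, `DegenerateInputError`, `GeometryError`) rather than
returning silently wrong numbers: identically zero AIFs, single-class ROC
tables, constant Spearman inputs, empty masks, all-excluded reports,
non-unit reorientation axes. Floating-point ties in the Youden scan resolve
to the lowest threshold with a 1e-12 tolerance so the tie-break is
deterministic across vectorized and scalar evaluation orders.

## Known limitations

Single-input (LV) kinetics without extraction-fraction or dual-blood-pool
modelling; translation-only registration; fixed right-dominant territories;
the ABHC family matches the simulated artifact rather than scanner physics;
landmark detection requires either an RV structure or an explicit angle; the
17-segment variant, endo/epi layering and left-dominant validation are out of
scope. Clinical figures quoted as generator parameters (group means, the 200
cutoff) characterize the synthetic conditions, not a clinical validation of
this implementation.
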