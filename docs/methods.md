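# Methods

## The problem being modelled

Wide-field OCT probability (p-) maps flag pixels where an eye's RNFL is
thinner than an age-corrected healthy reference.  In clinical practice a
glaucoma call from such a map starts from a red region near the temporal
half of the optic disc; but healthy eyes produce such regions too, because
the positions of the major arcuate fiber bundles and their blood vessels
vary between normal eyes.  The package implements the whole chain — a
synthetic scan generator, normative map construction, region/rule logic,
circumpapillary metrics and cohort evaluation — so the dissociation between
*artifact* (anatomical variation) and *damage* (fiber loss) can be studied
quantitatively, with ground truth known for every eye.

## Generative model of the thickness map

Scan geometry is the standard wide-field raster: 256 rows × 512 columns
covering 9 × 12 mm.  All positions are millimetres, row-major, origin at the
upper-left pixel, half-open pixel convention.  Retina view (top = superior
retina) is native; decision rules run in field view (vertical flip), right-eye
(OD) frame (left eyes mirrored).

Fiber trajectories follow a one-parameter arcuate family in a disc-centred
polar frame,

    φ(r) = φ₀ · exp(−β (r − r_d)),

where φ₀ is the entry angle at the disc boundary (measured from the
disc→fovea axis, superior positive), r the disc distance and β the arc
curvature (1/mm).  The horizontal raphe is a hard boundary — φ never changes
sign — and the model inverts in closed form (φ₀ = θ·exp(β(r−r_d))), so each
pixel knows the entry angle of the fiber above it and whole maps are
synthesised vectorised.

Thickness at a pixel is

    T = [ A(φ₀; σ_eff(r)) · (1 − defect(φ₀)) · age · e^(−(r−r_d)/λ) + V ] · pit + ε

with:

* **A**: angular profile — two wrapped-Gaussian arcuate ridges (amplitude
  125 µm, width 26°, peaks ±76°), a papillomacular plateau (48 µm, 42°) and a
  diffuse floor (58 µm).  These values give a double-hump TSNIT curve with
  G_cpRNFL ≈ 90 µm in healthy eyes.
* **σ_eff(r)**: bundle *fanning* — the angular width grows by 2°(of θ)/mm of
  disc distance.  Fanning is what confines a displaced bundle's mismatch to
  the neighbourhood of the disc: downstream, neighbouring bundles overlap
  and the gap fills in.  True fiber loss is multiplicative and is therefore
  visible along the entire trajectory.  This asymmetry is the mechanism
  behind the vertical midline rule, and the simulator is deliberately built
  around it.
* **defect(φ₀)**: a hard wedge in entry-angle space removing
  `depth_fraction` of neural thickness (vessels are spared).  Kinds: none,
  arcuate, diffuse temporal, combined.
* **age**: fractional decline of 0.2%/year about age 60 (≈ −0.2 µm/yr at
  100 µm), applied multiplicatively so the per-pixel age slope scales with
  local thickness.
* **λ = 4 mm** radial decay (fibers accumulate towards the disc).
* **V**: additive vessel ridges (26 µm, σ 0.15 mm) at fixed angular offsets
  from the bundle peaks, so displaced bundles carry their vessels.
* **pit**: foveal depression (Gaussian, σ 0.55 mm).
* **ε**: i.i.d. Gaussian noise, default σ = 3 µm, clipped at 0 — small
  relative to ~100 µm bundles; scan-quality artifacts (motion, segmentation
  failure) are intentionally out of scope.

The macular GCL+ layer is a fovea-centred donut (peak ≈ 85 µm above a 24-µm
base at 1.05 mm eccentricity) thinned by 0.85 × the defect attenuation of
the overlying trajectories within 3.2 mm of the fovea; it is unaffected by
bundle displacement, which is an RNFL/vessel phenomenon.

### Healthy variation and artifact mechanisms

Healthy anatomy is sampled per eye: bundle peaks ±76° (SD 8°), curvature β
0.25/mm (SD 0.10, truncated to [0.08, 0.5], independent per hemifield),
log-normal amplitude jitter (7%/10%/6% for bundles/plateau/floor), landmark
and disc-size jitter, ages uniform 40–80, half OS.  The curvature spread is
essential: it makes the normative band position increasingly uncertain away
from the disc, which (with fanning) is why anatomical mismatch is red near
the disc but inside normal limits at the midline.

A fraction `artifact_rate` of healthy eyes (defaults 7% in the normative
group, 11% in the prospective controls — the empirical frequencies the
study conditions prescribe) carries an explicit artifact mechanism:

* **arcuate** (65%): one bundle + vessels displaced 26–40° towards the
  papillomacular axis (clamped ≥ 42° from it, since displaced bundles remain
  arcuate), leaving a thickness gap on the high-angle flank of the normal
  ridge position;
* **temporal_Q** (25%): congenital thinning of the papillomacular plateau
  and temporal floor (scale 0.38–0.55), fading radially (Gaussian, 2.2 mm)
  because it is a property of the papillomacular fiber mass — so the red
  region hugs the temporal disc and maculopapillary sector without crossing
  the fovea line;
* **both** (10%): the combination.

The displacement magnitudes are free simulator parameters (no quantitative
anatomical measurements exist to pin them); they were chosen once so that
displaced bundles are unambiguous on p-maps while remaining within the
anatomically plausible range.

Glaucomatous defect bands by severity (wedge width, depth, 24-2 MD):
EG 20–38°, 0.40–0.65, MD −5.8…−0.8 dB; MG 40–70°, 0.60–0.80, −11.5…−6.3 dB;
AG 70–115°, 0.78–0.95, −20…−12.3 dB (half of AG eyes combined with diffuse
temporal loss).  Severity labels are consistent with the MD staging bands.

## Normative model and probability maps

Per-pixel ordinary least squares of thickness on age over the reference
cohort (slope fixed at 0 with a warning if the age span is under 10 years);
the full sorted residual table is kept at every pixel (no parametric
assumption — robust at n = 200, the conventional database size).  A new
map's percentile is the midrank of its age-corrected residual inserted into
the table: with r table entries below and s tied, p = (r + 1 + s/2)·100/(n+1),
so the smallest attainable percentile is 100/(n+1) (≈ 0.5% at n = 200) and
held-out eyes from the reference process are uniformly calibrated
(P(p < q) ≈ q).  Categories: abnormal ("red") below the 1st percentile,
borderline ("yellow") below the 5th — the universal commercial convention;
both thresholds configurable.  No spatial smoothing is applied (smoothing
would change region topology).  Only age is corrected; disc-size or
refraction corrections, if any exist in commercial devices, are not modelled.

The default experiment fits the model on the HC-norm group *including* its
artifact carriers and evaluates those same eyes against it, as a commercial
database is used in practice; an artifact eye can still be red where it is
the most extreme eye at a pixel.

## Regions and decision rules

Abnormal regions are 8-connected components of red pixels (configurably
red-or-yellow — the two phrasings of "abnormal region" both occur in
practice), discarding components under 0.1 mm² (single-pixel specks that
readers ignore).  Flags per region, computed in the field-view OD frame:

* **temporal-disc condition**: intersects the annulus within 1.0 mm outside
  the disc boundary, restricted to the half-plane containing the fovea.
  "Near" is qualitative in clinical reading; the halo width is configurable
  and echoed in outputs.
* **midline crossing**: contains pixels strictly beyond the vertical line
  through the fovea (on the side away from the disc) with ≥ 0.25 mm extent;
  contiguity across the line is guaranteed by connectivity.  The minimum
  extent operationalises the human judgement that one-pixel grazing does not
  count.
* **zones**: disc-centred sectors relative to the disc→fovea axis — temporal
  quadrant ±45°, superior arcuate (45°, 135°), inferior arcuate (−135°, −45°).

Taxonomy: *arcuate* if a qualifying region has ≥ 50% of its area in one
arcuate sector; *temporal_Q* if ≥ 50% temporal and it reaches the
maculopapillary sector (the ±45° wedge between disc and fovea, whose exact
clinical boundary is nowhere formally defined); *both* if both hold.  The
human consensus-of-readers step is replaced by these deterministic rules —
a deliberate operationalisation, which is what makes the pipeline testable.

The vertical midline rule returns positive iff a qualifying region crosses;
the combined variant runs the crossing test on connected components of the
union of the RNFL and GCL+ abnormal masks, which can only add positives
(per-eye monotone), capturing structural damage whose RNFL expression stops
at the midline but whose macular GCL+ loss continues nasally.

## Circumpapillary metrics

The profile samples the thickness map on the 3.4-mm-diameter circle around
the disc centre by bilinear interpolation at 256 equally spaced angles
(matching the B-scan count; the sample count is configurable), TSNIT order,
OD frame.  G_cpRNFL is the arithmetic mean.  A zero-width circle is used
(whether devices average over a band is unknown).  Percentile cutoffs use
the Weibull plotting position k/(n+1), consistent with the map percentiles;
the 5th percentile of the reference G_cpRNFL distribution is the
conventional abnormality flag.

## Visual-field machinery

Reliability: FP and FN errors < 15% and fixation losses < 33% (strict).
Abnormal 24-2: GHT outside normal limits and/or PSD with P < 0.05; abnormal
10-2: MD and/or PSD with P ≤ 0.05.  Perimetric glaucoma requires three
consecutive reliable abnormal tests in one series with the abnormality in
the same hemifield; the two pathways combine by plain disjunction.  Severity
bands from 24-2 MD: early ≥ −6 dB, moderate in (−12, −6), advanced ≤ −12
(the conventional reading of staging bands whose printed inequality signs
are ambiguous; boundary values go to EG and AG respectively, configurable in
interpretation but fixed here).  Hemifield persistence is evaluated on the
per-test summary field; raw pointwise fields are not modelled.  Eligibility:
BCVA 20/40 or better, spherical equivalent within ±6 D.

Reported percentages follow clinical-report rounding: half-up, one decimal
for specificity, nearest integer for sensitivities and frequencies.

## What the synthetic cohorts do and do not show

The generator reproduces the *mechanism* under study — anatomical variation
creating temporal-disc red regions that fail to cross the midline, versus
multiplicative loss that crosses — together with realistic grid geometry,
laterality handling and summary-metric distributions.  It does not emulate
speckle, segmentation error, media opacity, eye movement, high myopia, disc
tilt or population covariance structure beyond the parameters above; passing
tests therefore validate the pipeline's logic and the internal consistency
of the mechanism, not clinical performance on real scans.  Quantities that
emerge from the default conditions rather than being imposed: observed
artifact frequency among healthy eyes (≈ 4–9%, against carrier rates of
7/11%: not every displaced bundle clears its own reference database),
midline-rule specificity ≈ 99%, early-glaucoma sensitivity ≈ 60–90% across
seeds with moderate/advanced sensitivity at or near 100%.

## Numerical and testing notes

* Maps are float32; percentile computation broadcasts against the
  (n, 256, 512) float32 residual stack (~105 MB at n = 200).
* Cohort generation is seeded through `numpy.random.default_rng`; every eye
  draws a child seed, so cohorts are bit-reproducible and independent of
  evaluation order.
* Degenerate inputs: constant reference maps give zero residual tables
  (percentile 50 via midrank tie handling); pixels clipped at 0 µm create
  ties handled the same way; a circle that exits the frame raises an error
  naming the exceeded margin; insufficient reference counts (< 20 by
  default) are rejected.
* Tests use reduced-resolution grids (64 × 128 over the same 9 × 12 mm) for
  geometry properties — the model scales with physical size — and the full
  256 × 512 grid for the end-to-end experiment (254 + 62 eyes), which is the
  problem size the acceptance script also uses.  Property-based tests
  (hypothesis, derandomised) cover flood-fill equivalence, rule monotonicity
  under mask growth, rule nesting and confusion-count correctness.
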