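# Methods

`mtjquant` quantifies muscle tissue structure and function in the zebrafish
embryo model of muscular dystrophy. Its core is a multiscale edge-orientation
statistic for fluorescence micrographs of the myotendinous-junction (MTJ)
basement membrane; around it sit structural scores, motility scoring, the
group statistics used throughout, and a synthetic-data generator that makes
every stage testable at desk scale.

## The 2-D wavelet transform modulus maxima (2DWTMM) analysis

**Model.** A laminin-stained micrograph is treated as a nonnegative
intensity field `I(x, y)` with a known pixel size in µm. At each size scale
`a` (in µm) the analyzing wavelet is the pair of first partial derivatives
of an isotropic Gaussian of standard deviation `a`:

    T_a[I] = ∇(G_a * I),   G_a(x, y) ∝ exp(-(x² + y²) / 2a²)

computed by separable convolution with the sampled Gaussian and its
derivative (kernel radius 4σ, reflective boundaries). Each pixel carries a
modulus `M = √(gx² + gy²)` and an argument `A = atan2(gy, gx)` — the
direction of the maximum intensity gradient.

**Modulus maxima.** A pixel is a modulus maximum when `M` is at least the
bilinearly interpolated modulus one pixel forward along `A` and strictly
greater than the interpolated modulus one pixel backward (strict on exactly
one side, so a discrete plateau yields exactly one maximum per crossing),
and `M` exceeds a configurable quantile of the modulus grid (default 0.5)
that suppresses noise-floor maxima. A border margin of `ceil(3σ)` pixels is
excluded to keep padding artifacts out of the statistic. Maxima are chained
as 8-connected components; chains trace the edges of bright structures.

**Anisotropy factor.** The per-scale organization readout is the axial
resultant length of the maxima arguments:

    F(a) = (1/N) · ‖ Σ_k (cos 2A_k, sin 2A_k) ‖ ∈ [0, 1]

Angles are doubled because gradient orientation is axial data: the two
gradient vectors flanking one bright band are anti-parallel and must count
as the same orientation. `F = 1` iff all doubled angles coincide (perfectly
parallel bands); for `N` i.i.d. uniform arguments `E[F] ≈ √π / (2√N)`
(Rayleigh), so isotropic texture scores near zero. `F` is undefined (NaN
and flagged, never 0) when a scale yields no maxima. The default scale grid
is 1.88–4.02 µm in 6 logarithmic steps, the range over which laminin
organization is scored.

Consequences worth knowing: `F` is invariant to affine intensity changes
`αI + β` (modulus and quantile threshold both scale by `α`) and to 90°
rotation up to discretization (< 0.02 drift in practice). Maxima along one
chain are spatially correlated, so the effective sample behind `F` is
closer to the chain count than to `N`; small fields therefore fluctuate
more than the Rayleigh bound for `N` suggests. The per-scale `F` of two
groups is compared with a paired t test by replicate index, SEM error bars,
and star flags at 0.05 / 0.01 / 0.001; no multiple-testing correction is
applied across scales, matching the per-scale star convention of the
source assay.

**Open design points resolved here.** The verbal description of the
statistic ("sum of the vector angles") is ambiguous between an angle sum, a
plain vector resultant, and an axial resultant; the axial resultant is the
only reading that is bounded, intensity-invariant, and rewards parallel
band edges, so it is implemented, and only the *direction* of group
differences (organized > disorganized) is treated as a testable surface —
not absolute bar heights. `F` is computed over all maxima in the image; an
optional ROI mask restricts it when analysis should be limited to the MTJ
region. Zero-variance paired differences are reported as a "p < 1e-12"
flag instead of a division by zero.

## Structural muscle metrics

* **MTJ vertex angle** — the interior angle at the chevron vertex between
  the two arm vectors defined by three landmarks (dorsal arm end, vertex,
  ventral arm end), via the arccosine of the normalized dot product.
  Landmarks are inputs (manual placement or synthetic ground truth);
  polyline fitting is deliberately out of scope. The angle is invariant to
  rigid motions and arm swapping to 1e-9°.
* **Detachment incidence** — per embryo, 100 · detached segments / scored
  segments; groups summarized as mean ± SEM over embryos. "Muscle segment"
  and "myotome" are the same counting unit here.
* **MTJ failure fraction** — the same contract applied to failed / scored
  MTJs.
* **Mosaic attachment** — percent of transplanted donor cells detached,
  reported both unrounded and half-up rounded to one decimal (the
  convention that makes 10/523 print as 1.9% and 12/491 as 2.4%).

## Escape-response motility

A trial is a touch-evoked swim recorded in an arena of two concentric
circles (inner 5 mm, outer 10 mm diameter) with the embryo started at the
center; "leaving the field of view" is operationalized as crossing the
outer circle, i.e. 5 mm of radial displacement, with the embryo treated as
a point. Exit times are linearly interpolated on the radial distance
between the two samples bracketing the crossing (trajectories are sampled
at 1 ms, so sub-frame precision is meaningful). Among repeated pokes of one
embryo the most robust response is taken to be the fastest exit. For group
comparison, embryos that never exit receive the maximum exit time among
exiting embryos *after* the biological replicates of the experiment are
pooled — imputation never decreases a time, never alters an exiting
embryo's time, and is idempotent. Group means use the same paired-t
machinery as the anisotropy comparison; single-pair groups are flagged
non-computable (df = 0).

## Summary statistics and dosing

SEM is the sample standard deviation (n−1) over √n. The default test is a
two-tailed paired Student t test on per-replicate differences (df = n−1);
unequal group sizes fall back to an unpaired Welch test with an explicit
warning. `supplement_molarity` does the vitamin dosing arithmetic: 5 mg of
niacin (123.11 g/mol) in 6 L is 6.77 µM; 10 mg of β-NAD (663.43 g/mol)
makes ~1.005 mL of a 15 mM stock.

## Synthetic data: what it emulates and what it does not

The generator renders what the downstream analyses assume, not biological
realism:

* **Chevron micrographs.** MTJ bands are two straight arms meeting at a
  vertex (the V shape of healthy somite boundaries), repeated every
  `band_spacing` µm along the anterior-posterior axis. Disorganization is
  modeled as contiguous erased arcs of band ("holes" in the basement
  membrane, drawn 2–6 µm long until the target erased fraction is met),
  off-band speckle puncta (Poisson count per 100 µm², Gaussian blobs of
  σ 0.4 µm), then Gaussian blur and additive Gaussian noise clipped at
  zero, applied last. Ground truth (post-hole band mask and per-chevron
  landmark triples) reflects the pre-noise geometry. Defaults: 512×512 px
  at 0.3 µm/px (configurable, not canonical — the source images publish no
  pixel size), vertex angle 100° (between the printed group means of ~103°
  and ~108°), band spacing 30 µm (approximate embryonic somite pitch),
  band width 1.5 µm, blur 0.5 µm, intensity 1000 with noise SD 20. Not
  modeled: 3-D stacks, photobleaching, two-channel imaging, Poisson shot
  noise, curved boundaries, or any biomechanics of detachment — so passing
  tests show the *statistic* behaves as designed, not that real dystrophic
  tissue will score at any particular F.
* **Cohort tables.** Per-embryo detached-segment counts are
  Binomial(segments, p_detach) draws — the sampling structure behind
  percent-incidence bars, with no overdispersion between embryos.
* **Escape trials.** Responders swim in a straight line from the center at
  a speed drawn from a truncated normal, sampled at 1 ms; non-responders
  (Bernoulli) are stationary. Real escape responses are curved and burst-
  like; straight lines suffice because only the radial crossing time is
  scored.

All generators are bit-deterministic for a fixed seed.

## Numerical choices and problem sizes

Convolution kernels are sampled (not integrated) Gaussians with radius
`int(4σ + 0.5)`; scales below twice the pixel size are rejected as
unresolvable. Bilinear interpolation is used for the directional maxima
test; ties on plateaus break toward the backward-strict side. The
brute-force oracles in the test suite (direct double-loop convolution,
exhaustive directional scan, BFS flood fill, literal doubled-angle vector
sum) are written independently of the vectorized implementations and agree
to 1e-8 relative (convolution), exactly (maxima sets, chain counts), and
1e-12 (F).

Verification runs use deliberately modest problem sizes chosen as the
package's own test conditions: 256×256 crops (same scene parameters) for
the organized-vs-disorganized cohorts (8 images per group, 20 repetitions,
7 scales), 512×512 for isotropic-noise calibration where chain-count
effects matter, 500 embryos for binomial recovery, and 100 seeded runs of
20-embryo cohorts for the motility power check.

## Known limitations

* Absolute F values depend on the floor quantile, noise level, and field
  size; only relative comparisons under a shared configuration are
  meaningful.
* The MTJ angle uses three landmarks; curved or U-shaped junctions are
  summarized by their secant arms.
* Imputation ties non-responders to the slowest observed exit, so a group
  with many non-responders has its mean bounded by the recording's worst
  responder, not by the (unobservable) true latency.
* The synthetic scenes cannot validate segmentation or staining variation;
  they validate the measurement chain downstream of imaging.
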