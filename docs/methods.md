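# Methods

`nirspath` models how pediatric head anatomy shapes continuous-wave fNIRS
measurements. It couples a parametric synthetic-head cohort generator to a
voxel Monte Carlo photon transport engine, estimates differential and
partial pathlength factors (DPF, PPF) per 10-5 scalp position, and carries
the results through the modified Beer-Lambert law (MBLL) and group-level
map statistics. This note records the model, its assumptions, the defaults
and why, and what the synthetic cohort can and cannot say about real heads.

## The quantities

For a source-detector pair separated by scalp distance `L`, the MBLL reads

    dOD_l = (sum_i eps_i,l dc_i) * L * DPF_l * PVF_l
          = (sum_i eps_i,l dc_i) * L * PPF_l

`DPF` converts geometric separation into effective photon pathlength
through all tissue; `PPF = DPF * PVF` is the brain-only part, the term that
actually scales measured hemodynamic amplitudes. Both are unitless;
concentrations are in uM, lengths in mm, and `dOD` is log base 10
throughout (the extinction matrix embedded in `mbll` is log10-based, so
forward and inverse are mutually consistent; mixing bases is the classic
silent error this pinning avoids).

## Synthetic head cohort

Each subject is a full tri-axial ellipsoid with nested shells (scalp,
skull, CSF, brain; voxel labels 1-4, air 0), voxelized at 1.0 mm by
default. Aspect ratios are fixed at RL:AP:SI = 0.96:1.04:1.00; scale
comes from the sampled head circumference. Regional structure is added by
smooth raised-cosine patches on top of per-subject base thicknesses:

| parameter | default | role |
| --- | --- | --- |
| skull base thickness | lognormal, median 2.585 mm, log-SD 0.30, range 1.1-9.6 | cranial vault |
| CSF base thickness | normal, 5.1 +/- 0.70 mm, range 3-9 | subarachnoid layer |
| scalp-to-cortex depth | 10.17 +/- 1.2 mm (sampled compositionally) | scalp + skull + CSF |
| crown skull multiplier | x2.5 over a 65 deg posterior-superior cap | crown/posterior skull 2-3x thicker than frontal/temporal |
| vertex CSF bonus | +3 mm over a 45 deg cap just anterior of the vertex | thick CSF around the vertex / sagittal sinus region |
| frontal depth offset | +2.5 mm over a 40 deg frontal patch, females only | frontal-sinus-related sex difference in cortical depth |
| sex ratio | 46/90 male | cohort composition |
| age | 94.2 +/- 16.8 months, truncated to [58, 131.4] | demographics |
| head circumference | 38.8 +/- 2.2 cm, coupled to age with R^2 ~ 0.176 | head size |

Depth is sampled *compositionally* (depth = scalp + skull + CSF, with the
scalp layer absorbing the residual variance and the circumference-depth
coupling of 0.30 mm/cm): the nesting invariant `depth >= skull + CSF`
then holds by construction and the three sampled medians stay calibrated
to the cohort values without rejection. The quoted published spreads are
whole-map robust statistics that include spatial variation; the regional
patches supply most of that spread, which is why the per-subject base
spreads above are narrower than the printed figures.

**Head size and the circumference convention.** The cohort's printed
"head circumference" (~38.9 cm) is measured at the cross-section reached
10% of the way up the preauricular coronal arc, and is far below a true
head circumference at this age. No convex head can have a closed
circumference only ~5% longer than its over-the-vertex arcs, so the three
printed arc statistics are not jointly realizable as literal geodesics.
The generator takes the printed value at face value *under its stated
convention*: subject scale is chosen so that the 10%-elevation ring
perimeter equals the sampled circumference, giving scalp radii around
65 mm. `measure_arcs` then reports the circumference (reproducing the
printed distribution by construction) and the honestly measured AP/RL
vertex arcs, which at this scale are ~20 cm rather than the printed
~37/34.5 cm. The alternative — inferring a "true" head size — was
rejected as speculation about an upstream measurement convention.

## Photon transport

A standard continuous-absorption voxel Monte Carlo walk (see the module
docstring in `photon_transport` for the event loop):

* exponential free paths with `mu_s = mu_s'/(1-g)`; the remaining
  scattering optical depth is carried across voxel and tissue boundaries,
  which is essential in CSF (`mu_s ~ 0.09 /mm`, free paths longer than the
  layer);
* Henyey-Greenstein deflection with the local `g` (0.89 for all tissues);
* weight `exp(-sum mu_a,t L_t)` from per-tissue path accumulators, so
  partial pathlengths are tallied exactly with low variance;
* unpolarized Fresnel reflection/refraction at voxel faces where `n`
  steps (1.45 tissue, 1.33 CSF, 1.0 air), including total internal
  reflection; exiting photons are recorded without a numerical-aperture
  cut; specular reflection at launch is skipped (the photon starts just
  inside the scalp);
* Russian roulette below weight 1e-4 (survival 0.1) and a 1500 mm total
  path cap.

Per-photon counter-derived RNG substreams (splitmix64-seeded
xorshift128+) make runs bitwise reproducible for a given (seed, config)
and order-independent. Energy bookkeeping `launched + roulette_gain =
detected + absorbed + terminated + escaped` is checked to 1e-6 on every
run (roulette survival creates weight by design; it appears explicitly in
the balance).

Default photon count is 1e6 per source (a desk-scale budget; the
reference analysis this emulates used 5e7). Channel intensities at 30 mm
then carry a few-percent Monte Carlo error, and fitted DPF values move by
roughly +/- 0.1-0.2 between seeds.

Detection pools exits within a 1.5 mm radius of each 10-5 position
(`aperture` mode; a `nearest`-partition mode exists for conservation-style
analyses). Source-detector separation is the scalp arc distance computed
on the smooth ellipsoid.

## 10-5 layout

346 named positions: the 343-electrode extended 10-5 grid plus the Nz,
LPA, RPA fiducial points. Positions are constructed by proportional arc
subdivision — midline nasion-inion arc at 5% steps (21 rows), and at each
row a transverse plane-section contour from the left equator point through
the midline point to the right equator point, subdivided at 10% of each
hemicontour (lateral slots z, 1h, 1, 3h, ..., 9; temporal prefixes FFT/FT/
FTT/T/TTP/TP/TPP for slots 7-10 of the central rows; legacy aliases
T3-T6, periauricular A1/A2/M1/M2, and equator-level I1/I2 points complete
the conventional set). Analytic positions are snapped to the nearest
scalp-surface voxel center with lowest-flat-index tie-breaking, so the
naming and count are invariant to voxel size.

## DPF/PPF estimation

Per source, channels with separations in [10, 40] mm and at least 10
detected photons enter an iteratively reweighted least-squares fit with
the Tukey bisquare weight (c = 4.685), seeded by intensity weights so
sparsely sampled long channels do not dominate. Late IRLS iterations are
damped (iterate averaging) because scale re-estimation can produce a
small limit cycle; the fixed point is unchanged.

**Estimator choice.** On these four-layer heads the transparent CSF shell
channels light laterally, so mean path vs separation is markedly concave
over 10-40 mm (path/rho falls from ~8 at 11 mm to ~4.5 at 40 mm). A
straight line with a free intercept then puts most of the signal into the
intercept (~70 mm) and its slope (~2.7) no longer measures path per unit
separation — the quantity DPF is defined to be. The default estimator is
therefore the *through-origin* robust slope, the direct rendering of
`path = DPF * L`; the free-intercept variant (`intercept=True`) and the
weighted mean-ratio variant (`mode="ratio"`) are provided, and the
concavity itself is reported via the fit diagnostics. On the
cohort-median geometry the default estimator gives DPF ~ 6.0-6.3 at
690 nm, within the published cohort range (5.38-6.84).

## Topographic projection and group statistics

Heads are registered to the template by similarity (Umeyama) alignment of
nasion and both preauricular points, optionally refined by ICP against
the template surface. Scalar fields are read along the inward smooth
ellipsoid normal (staircase-free), projected through a far-side
vertical-perspective azimuthal projection (viewpoint 1.4 normalized head
radii beyond the antipode on the vertex axis, injective to a 108 deg
polar angle, radius normalized at the horizon) and linearly interpolated
onto a 64 x 128 equidistant polar grid (grid resolution and kernel are
conventions, configurable). Group maps are cellwise medians requiring
>= 50% valid subjects per cell.

The robust spread convention is `0.67499 * MAD` exactly as the source
cohort printed it; the conventional consistency-corrected estimator
(`1.4826 * MAD`) is available behind a flag. Regression t-maps use
df = n - 2 for p-values and also report n - 1, since published t-maps for
n = 90 quote 89 df. The two-way ANOVA is the type-II main-effects F test
(`y ~ cell + group` vs `y ~ cell`) on the long-form data. No multiple-
testing correction is applied by default (matching the source analysis);
an FDR pass is trivial to add downstream from the returned p-maps.

## What the synthetic cohort does and does not emulate

It emulates: the printed layer-thickness and depth distributions and
their regional patterns; the female frontal depth excess (2-3.5 mm); the
weak age-circumference coupling; head-size scaling; and the full
measurement chain from photon transport to look-up tables.

It does not emulate: cortical folding (the brain surface is smooth, so
gyral crowns never approach the skull — absolute PPF comes out around
0.8-1.5 at the median geometry versus ~1.8-2.5 on folded MRI anatomy,
and the brain-path fraction PVF is ~0.15 versus ~0.4); interrupted or
position-dependent CSF gaps (the uninterrupted transparent shell
maximizes lateral channeling, strengthening the path-separation
concavity and making DPF sensitive to CSF thickness); skull
inhomogeneity; or any subject/spatial variability in optical properties
(bulk per-tissue constants only). Consequently, *directional* effects
(PPF falls with depth; females lower frontal PPF; deeper regions less
sensitive in dB) transfer to real anatomy, while absolute PPF values and
wavelength orderings that hinge on the brain-path fraction do not
necessarily transfer — at the median geometry this model's DPF is not
higher at 690 nm than at 830 nm, unlike the folded-anatomy result; see
the ledgered acceptance analysis and the limitations below.

## Numerical choices and degenerate inputs

* Voxel size must resolve the thinnest layer (>= 1 voxel) or
  `build_head` raises `ResolutionError`.
* Layer boundaries are radial offsets from the scalp surface; radial vs
  normal thickness differs by <2% at these aspect ratios.
* Zero-spread distributions return their means exactly (degenerate
  sampling is deterministic).
* Channels with zero detections carry intensity 0 and NaN means and are
  excluded from fits; fits need >= 3 usable channels.
* Tie-breaks: optode snapping picks the lowest flat voxel index among
  equidistant surface voxels.
* The diffusion-theory oracle used in tests evaluates the
  extrapolated-boundary semi-infinite CW reflectance and its mu_a
  derivative numerically; Monte Carlo agrees within 10% at 20-40 mm.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run at desk scale by design:
1e6 photons for the median-geometry DPF, 1.5-7e5 for wavelength and
estimator comparisons, 8e4-1.5e5 per head for parameter sweeps, and 2e4
photons per subject for the 90-subject planted-sex-effect pipeline,
where the detection statistic is the partial-volume fraction (the
planted contrast, ~14% at the frontal patch, then stands well clear of
the Monte Carlo noise).
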