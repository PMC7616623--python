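# Methods

## Scope and model

`tiltmet` quantifies how much the *directional* spectral variability of a
lighting environment helps an observer distinguish surface reflectance pairs
that are metameric (indistinguishable) at some surface orientation. The
physical scene is deliberately minimal: a single matte (Lambertian) planar
surface, no occluders, no interreflections. For that geometry the reflected
radiance at a tilt with unit normal **n** is exactly

    L_out(λ) = R(λ) E(n, λ) / π,
    E(n, λ)  = ∫_sphere L(ω, λ) max(0, n·ω) dω,

so a general light-transport renderer is unnecessary: direct cosine-weighted
integration over the environment map is physically equivalent and
deterministic. This equivalence is the package's replacement for path-traced
rendering and is validated against a Monte-Carlo hemisphere-sampling oracle
(agreement ≲ 0.1% at 64×128 map resolution; the acceptance bound is 2%).

### Quadrature

Environment maps are equirectangular: rows are inclination θ ∈ [0, π] from
the zenith, columns azimuth φ ∈ [0, 2π), pixel solid angle
Δω = sin θ Δθ Δφ (midpoint rule; the sphere total is within 1% of 4π at the
minimum supported 8×16 resolution). For each normal, the cosine-weighted
pixel weights are renormalized to sum to π — their exact continuous value.
This makes a direction-independent radiance field integrate to π·L at
*every* normal to machine precision, so the null experiment (a uniform
environment can never make a pair's ΔE tilt-dependent) holds exactly rather
than up to ~10⁻³ grid anisotropy, while directional integrals change by less
than the raw quadrature's own error.

### Tilt sampling

The 81 tilts default to a deterministic Fibonacci spiral over the upper
hemisphere (zenith included exactly; minimum pairwise separation ≈ 9°). A
`slant_azimuth` mode (zenith + 8 slant rings × 10 azimuths at 11.25°
increments) is available for sensitivity analysis. The exact tilt set is a
free design choice; results depend on it only through the min/max of ΔE over
a reasonably dense hemisphere cover.

### Colorimetry and appearance

Spectra live on a uniform wavelength grid, default 400–700 nm at 5 nm
(61 samples, configurable); all inputs are resampled linearly on load, with
extrapolation forbidden. Tristimulus integration uses the bundled CIE 1931
2° observer (abridged 10 nm tabulation, interpolated), with
Y = 683 lm/W · Σ ȳ L Δλ for absolute luminance.

Appearance is CIECAM02 → CAM02-UCS, implemented in full (CAT02 adaptation
with degree D, Hunt–Pointer–Estévez cone space, F_L compression, achromatic
response, J/M/h; J′ = 1.7J/(1+0.007J), M′ = ln(1+0.0228M)/0.0228,
a′ = M′cos h, b′ = M′sin h), verified against the published worked examples
to 0.01 in J and 0.1° in h. ΔE is the unweighted Euclidean distance in
(J′, a′, b′). Viewing conditions are scene-derived: W_p is the mean XYZ over
all 81 tilts of a perfect-white (R ≡ 1) rendering, L_A the solid-angle-
weighted mean luminance over map pixels, Y_b = 100·L_A/Y(W_p) clamped into
(0, 100], surround "average". One consequence worth knowing: CIECAM02 hue is
only *approximately* invariant to radiance scaling (the per-channel response
compression saturates), so pure intensity gradients still move colors in UCS
through J′ — by design of the appearance model.

### Dichromat simulation

Brettel-style projection in HPE cone space: the missing cone's signal is
replaced so the stimulus lands on one of two half-planes hinged on the
equal-energy-white axis with monochromatic anchors at 575/475 nm
(protan, deutan) or 660/485 nm (tritan), all computed from the bundled CMFs
on the working grid (so the flat-spectrum white is an exact fixed point).
The two half-planes are separated by the plane spanned by the white axis and
the **missing cone's axis**; because the projection moves stimuli parallel to
that axis, side classification is projection-invariant and the transform is
exactly idempotent — the naive "S/M for both protan and deutan" rule is not.

The dichromat's viewing conditions use the Brettel-projected scene white
(renormalized to Y = 100), on the reasoning that the adapted white must be a
color the dichromat can see; L_A and Y_b are luminance-based and carry over.
The alternative order (transform after white normalization, keep the
trichromatic W_p) is available via `RunConfig.dichromat_white =
"trichromat_white"`.

## Statistics

Per scene, observer and threshold θ: a pair is a *candidate* metamer when
min ΔE over tilts < θ, *solved* when additionally max ΔE ≥ θ, *never
distinguishable* when max ΔE < θ; by construction
n_solved + n_never = n_candidates. proportion_solved = 100·n_solved/
n_candidates is reported as missing (not 0) when there are no candidates.
θ defaults to 0.36 (mean MacAdam JND radius in CAM02-UCS) and is swept over
{0.36, 0.5, 1.0, 2.0}; the candidate count is non-decreasing in θ.

The absolute increase max−min is histogrammed over **all** pairs; the
relative increase (max−min)/min·100 excludes pairs with min ΔE = 0 (division
undefined; their count is logged — constructed metamers make this case
routine). Histograms use bin width 1 with origin 0; the mode is the center of
the most populated bin, ties resolved to the lowest bin; storage is sparse
because the relative metric is heavy-tailed when min ΔE is tiny. Across-scene
aggregation is the unweighted mean ± sample SD per scene label
(outdoor/indoor).

The mixed-design (split-plot) ANOVA on per-scene proportions — scene type
between, observer type within — is delegated to `pingouin.mixed_anova`, with
Bonferroni-corrected paired comparisons from `pingouin.pairwise_tests`. On a
complete 10-scene (6 outdoor + 4 indoor) × 4-observer table the dfs are
(1, 8) for scene type and (3, 24) for observer and interaction. Both partial
η² and generalized η² are reported, since the two conventions differ and
neither is a superset of the other. An all-constant table is short-circuited
to F = 0 (the F ratio is formally 0/0 there). The test suite cross-checks F
values against an independent textbook sums-of-squares implementation.

Deduplication of the input corpus is a deterministic greedy pass in input
order: a reflectance is dropped when its spectral Pearson correlation with
any already-retained reflectance exceeds 0.999; afterwards no retained pair
exceeds the threshold. Constant spectra (undefined correlation) are retained
and logged.

## Synthetic data

The generator supplies the statistical structure the analysis assumes; it
makes no claim of reproducing any particular measured corpus.

**Reflectances** are clipped sums of positive Gaussian bumps (width ~60 nm)
over a flat base, with per-category priors (flower/fruit/skin/leaf/man-made;
default mix dominated by man-made samples) controlling base level, bump
count and peak positions. They are smooth (max first difference < 0.15 per
5 nm) and bounded in [0, 1]. A configurable fraction (default 5%) are
near-duplicates — a parent plus low-amplitude smooth noise with r > 0.999 —
to exercise deduplication; independent draws are redrawn on the rare event
they accidentally correlate above 0.999 with an earlier sample.

**Environments.** Outdoor maps are two-zone: sky hemisphere at a CIE
daylight-series spectrum (default 10000 K), a solar disc at a warmer
daylight spectrum (default 5000 K) scaled by a sun/sky radiance contrast
(default 30), and a ground hemisphere reflecting 20% of the mean sky
radiance. The disc radius defaults to 10° — far larger than the physical
sun, so that it resolves at the default 32×64 grid; its irradiance share is
governed jointly by radius and contrast. Indoor maps are a single Planck
spectrum (3000–4000 K, incandescent-like; the daylight series is invalid
below 4000 K) with a smooth seeded directional *intensity* modulation
(max/min ratio = `contrast`, default 2): indoor directionality is
luminance-only, with a single chromaticity everywhere — the limiting case in
which exact metamers can never be resolved chromatically. Maps are scaled so
the solid-angle-weighted mean luminance equals a calibration target
(3000 cd/m² outdoor, 300 cd/m² indoor — typical adapting luminances).
Daylight reconstructions land within 0.002 chromaticity of the CIE daylight
locus.

**Constructed metamers** use the metameric-black device: for a chosen tilt
and observer, the matrix A mapping reflectance to sensor responses under
that tilt's irradiance (3×61 for the trichromat; the two surviving HPE cone
rows for a dichromat) has a large null space; a smooth random perturbation
is projected onto it and added to a base reflectance at the largest
amplitude (≤ 0.25) that keeps values in [0, 1]. The pair's responses agree
at the construction tilt to ~10⁻¹² and generically differ elsewhere whenever
the environment is spectrally directional. Under the default outdoor map,
94/100 seeded draws are both candidates and solved at θ = 0.36 (the
remainder differ too little at other tilts); under a uniform or
intensity-only environment the pair matches at every tilt, as linearity
demands.

What the generator does **not** emulate: measured reflectance statistics
(so absolute candidate counts and solved percentages are not comparable to
any field corpus), spatially complex skies, occlusion/interreflections, and
spectrally varying indoor directionality. Passing tests therefore establish
the correctness and internal consistency of the machinery — not field
percentages.

## Problem sizes and reproducibility

Default study sizes keep everything desk-fast: corpora of 100–250
reflectances (10³–10⁴ pairs per scene; the formula n(n−1)/2 is exercised up
to the 20,132-surface corpus scale arithmetically), 32×64×61 environment
maps, 81 tilts, 10 scenes × 4 observers × 4 thresholds. The acceptance
script (~10 s) augments a 160-sample natural corpus with 4 constructed
metamer pairs per scene so that every scene×observer cell of the ANOVA
table has candidates.

All randomness flows through explicitly seeded `numpy` generators; pair
iteration order is canonical (sorted ids); rerunning any configuration
reproduces results bit-for-bit, and each run writes a provenance record
(config, seeds, versions) sufficient to do so.

## Known limitations

- Single-plane scene: no occlusion, interreflection or specularity; results
  are upper bounds on tilt-driven discriminability for glossy/complex
  objects.
- CIECAM02 is used outside the photopic-office conditions it was fitted on
  when L_A is very large; the "average" surround is fixed.
- The Brettel projection models complete dichromacy only; anomalous
  trichromacy is out of scope.
- The indoor generator's intensity-only directionality is a deliberate
  limiting case, not a measured interior.
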