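# tiltmet

**Does the directional structure of real-world lighting resolve illuminant
metamerism?** Two surfaces with different spectral reflectances can reflect
physically different light yet elicit identical cone signals under one
illuminant — and distinct signals under another. Under a single uniform
illuminant this *illuminant metamerism* is a hard limit of tri- (or di-)
chromatic vision. But real lighting environments are directional: a tilted
surface facing the sun samples a different illuminant spectrum than the same
surface facing the sky. `tiltmet` quantifies how often that directional
variability turns indistinguishable surface pairs into distinguishable ones,
for normal trichromats and for protan, deutan and tritan dichromats.

It is written for vision scientists and colorimetry engineers who want a
tested, reproducible implementation of the full chain: hyperspectral
environment maps → Lambertian tilt-series rendering → CIECAM02-UCS appearance
→ dichromat simulation → metamerism-resolution statistics — plus a synthetic
data generator so the whole pipeline runs and is testable without any
external corpus.

## The model

For a matte planar surface with reflectance R(λ) and unit normal **n** inside
an environment with directional spectral radiance L(ω, λ), the reflected
radiance is

    L_out(λ) = R(λ) · E(n, λ) / π,   E(n, λ) = ∫ L(ω, λ) max(0, n·ω) dω

(direct cosine-weighted irradiance integration; exact for an unoccluded
plane). Each surface is rendered at 81 tilts spanning the upper hemisphere,
converted to CIE 1931 XYZ, optionally projected onto a dichromat's gamut with
the Brettel half-plane model (anchors 575/475 nm for protan and deutan,
660/485 nm for tritan, hinged on the equal-energy-white axis in
Hunt–Pointer–Estévez cone space), and mapped to CAM02-UCS (J′, a′, b′) under
scene-derived viewing conditions: W_p is the mean XYZ of a perfect-white
surface over the 81 tilts, L_A the solid-angle-weighted mean luminance of the
map, Y_b = 100·L_A / Y(W_p), surround "average".

For every unordered surface pair the color difference
ΔE = ‖(J′,a′,b′)₁ − (J′,a′,b′)₂‖ is evaluated at all 81 tilts. With a
discriminability criterion θ (default 0.36, the mean MacAdam-ellipse JND
radius in CAM02-UCS):

- **candidate metamer** — min ΔE < θ at some tilt;
- **solved** — candidate with max ΔE ≥ θ at another tilt;
- **never distinguishable** — max ΔE < θ at every tilt;
- discriminability gains: absolute increase `max ΔE − min ΔE` and relative
  increase `(max ΔE − min ΔE)/min ΔE × 100`, summarized per scene by
  histogram modes (bin width 1, ties to the lowest bin).

Per-scene solved proportions feed a split-plot ANOVA (scene type
outdoor/indoor between scenes, observer type within scenes) with
Bonferroni-corrected pairwise observer comparisons.

## Worked example

```python
from tiltmet import (RunConfig, run_pipeline,
                     ReflectanceGeneratorConfig, EnvironmentGeneratorConfig)

cfg = RunConfig(
    corpus=ReflectanceGeneratorConfig(n_samples=120, duplicate_fraction=0.05, seed=42),
    environments=[
        EnvironmentGeneratorConfig(kind="two_zone_outdoor", seed=0, name="meadow"),
        EnvironmentGeneratorConfig(kind="low_contrast_indoor", seed=1, name="office"),
    ],
    thresholds=(0.36, 2.0),
    out_dir="results/demo",
    seed=42,
)
res = run_pipeline(cfg)
df = res["summaries"]
print(df[df.threshold == 0.36][["scene", "observer", "n_pairs", "n_candidates",
                                "n_solved", "proportion_solved", "abs_mode"]])
```

prints (trimmed):

```
 scene   observer  n_pairs  n_candidates  n_solved  proportion_solved  abs_mode
meadow trichromat     6441             0         0                NaN       6.5
meadow     protan     6441             1         1         100.000000       5.5
meadow     deutan     6441             2         2         100.000000       6.5
meadow     tritan     6441             2         2         100.000000       4.5
office trichromat     6441             1         1         100.000000      16.5
office     deutan     6441             3         2          66.666667      14.5
```

Reading: the 120-sample corpus deduplicates (spectral Pearson r > 0.999) to
114 surfaces = 6441 pairs. Under the sun/sky "meadow" map, every accidental
metamer of the dichromat observers is solved by tilting
(`proportion_solved = 100`), and a typical pair's ΔE grows by 4–7 UCS units
between its best and worst tilt (`abs_mode`). Chance metamer candidates are
rare at this corpus size — the full-scale analysis uses ~2×10⁸ pairs. Each
run also writes `summaries.csv`, `aggregates.csv`, histogram CSVs and a
`provenance.json` that reproduces the run bit-for-bit.

A CLI mirrors the library: `tiltmet fixture`, `tiltmet simulate --config
cfg.json`, `tiltmet run --config cfg.json --seed 1 --threshold 0.36 --out
results`.

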