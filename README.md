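# ihcfusion

Computer-assisted quantification of DAB immunohistochemistry on
brightfield image tiles, with conditional fusion of two markers mapped
on adjacent tissue sections.

Glioblastomas recruit large populations of microglia and bone-marrow-
derived macrophages whose markers — IBA1 (pan-microglia/macrophage,
cellular staining) and CD163 (infiltrating macrophages, often deposited
diffusely and extracellularly in necrosis) — diverge strikingly across
a single tumor.  Assessing where two markers stained on *adjacent*
sections agree or disagree is exactly the kind of whole-slide, spatial
comparison that defeats the eye.  `ihcfusion` implements the analysis
end to end for neuropathology image analysts:

1. **Stain extraction** — brown (DAB-positive) regions are found by
   k-means clustering of pixel colors in CIELAB, with the number of
   clusters chosen automatically (silhouette score) and clusters kept
   when their center is brown and darker than a threshold:
   hue ∈ [10°, 50°], S ≥ 0.15, V ≤ 0.75 by default.  A tissue mask
   excludes glass so positive fractions refer to tissue.
2. **Heatmaps** — tiles are divided into 16 × 16-pixel patches; each
   patch scores the mean chromogen darkness (1 − V) over its
   DAB-positive pixels, max-normalized per tile and rendered on a
   turquoise (low) → red (high) scale.
3. **Registration + fusion** — the section pair is aligned rigidly
   (phase correlation + rotation search); the two binarized heatmaps
   are fused conditionally: high in both → red, high in exactly one →
   white (discrepant), low in both → turquoise.
4. **Statistics** — Pearson/Spearman correlation between the markers at
   patch granularity plus per-region (necrosis / pseudopalisading rim /
   viable) contrasts.

Because the original slides are not deposited anywhere, the package
ships a first-class **synthetic histology generator**: seeded,
ground-truthed pairs of pseudo-adjacent tiles with hematoxylin
counterstain, cellular/diffuse/rim DAB geometries and a known rigid
inter-section transform, rendered by Beer–Lambert stain mixing.  Every
pipeline stage is tested against the generator's planted truth.  See
`docs/methods.md` for models, parameters and limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on the demo
configuration (a 1024² section pair, one necrotic core covering 25% of
tissue, IBA1-like cellular marker vs. CD163-like diffuse marker,
planted transform (7, −3) px @ 1°):

```bash
python analysis/01_simulate_tiles.py --seed 0
python analysis/02_extract_dab.py
python analysis/03_build_heatmaps.py
python analysis/04_register_and_fuse.py
python analysis/05_marker_statistics.py
```

which prints, among other things:

```
IBA1   k=2  positive=0.0722  truth=0.0722  IoU=1.000
CD163  k=2  positive=0.1713  truth=0.1715  IoU=1.000

estimated transform  dx=+7.00 dy=-2.93 rot=+1.00 deg (score 0.147)
planted transform    dx=+7.00 dy=-3.00 rot=+1.00 deg
fusion classes: {'background': 403, 'concordant_low': 2154,
                 'concordant_high': 307, 'discordant': 1232}

pearson r = +0.031, spearman rho = +0.086 over 3693 co-tissue patches
  region  n_patches   mean_a   mean_b  diff_b_minus_a
necrosis        936 0.123730 0.508050        0.384320
palisade        115 0.748230 0.531099       -0.217131
  viable       2641 0.500514 0.183835       -0.316679
```

Reading this: the extractor recovers each marker's planted positive
fraction essentially exactly (7.2% of tissue for the cellular marker,
17.1% for the diffuse one); registration recovers the planted section
offset to a tenth of a pixel; and the fused map is dominated by
discordance (1232 white vs. 307 red patches, global r ≈ 0.03) with the
direction the histology leads one to expect — the diffuse marker's mean
intensity exceeds the cellular marker's inside necrosis (+0.38) while
the cellular marker dominates the rim and viable tissue.
`analysis/06_recovery_experiments.py` repeats the recovery measurements
across seeds.

A CLI exposes the same stages on your own tiles
(`ihcfusion simulate|extract|heatmap|fuse|stats|run`), configured by a
strict JSON document; `ihcfusion run --out DIR --seed N` executes the
whole pipeline and writes a manifest of every artifact.

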