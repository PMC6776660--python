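# dichroma

Sexual dichromatism and color-diversity analysis of reflectance spectra
under a tetrachromat receptor-noise visual model.

Many lizards look monochromatic to us but not to each other: diurnal
lizards carry four cone classes, including one sensitive to near-UV, so
"does this species have sex-specific coloration?" has to be answered in
the *receiver's* color space, not in RGB. `dichroma` implements the
complete analysis chain used in sensory-ecology studies of body-region
coloration:

1. **Spectra processing** — wide-CSV reflectance spectra (300–700 nm) are
   validated, LOESS-smoothed (span 0.2), clamped at zero and normalised
   to proportion reflectance.
2. **Visual modelling** — quantum catches
   `Q_i = ∫ R(λ) I(λ) S_i(λ) dλ` for the four single cones (u, s, m, l)
   and the double cone, under a blue-sky or ideal illuminant, with cone
   sensitivities synthesised from the Govardovskii A1 nomogram or loaded
   from CSV. Chromatic distances `dS` follow the Vorobyev–Osorio
   receptor-noise-limited model on log catch ratios with per-channel
   noise `e_i = ω/√n_i`; achromatic distances `dL = |ln(Q_D^a/Q_D^b)|/e_D`
   use the double cone. Both are in just-noticeable-difference (JND)
   units; three cone-proportion schemes (LWS-emphasis, equal, split
   dS/dL) are built in.
3. **Tetrahedral color space** — relative catches map into the color
   tetrahedron (achromatic point at the origin), where five diversity
   indices plus the UV centroid are computed: relative color volume
   (convex hull), color-span mean/variance, hue-disparity mean/variance,
   and mean UVS-cone stimulation.
4. **Dichromatism detection** — per body region, the pooled JND matrix is
   clustered by UPGMA; cuts at 2–6 clusters are scanned after singleton
   (outlier) removal, and a region is called dichromatic if some cluster
   is ≥90 % one sex, holds ≥10 % of the region's samples and sits ≥2 JND
   from the rest.
5. **Randomization inference** — for each region and index, the observed
   male − female difference is tested against 1,000 sex-label
   permutations (significant when |observed| exceeds the 95th percentile
   of the |null| differences).
6. **Synthetic study generator** — a field dataset emulator (13 males,
   12 females, 10 body regions with realistic per-region sample counts,
   248 spectra per individual) with parametric color-patch archetypes
   and a ground-truth manifest of planted dichromatism, so the whole
   pipeline is testable without field data.

## Worked example

```python
from dichroma import RunConfig, run_pipeline

cfg = RunConfig(scenario="paper_like", scale=0.25, n_perm=1000,
                seed=7, outdir="results/demo")
result = run_pipeline(cfg)
print(sorted(result.flagged_regions("dS")))
print(result.dichromatism.head(4).to_string(index=False))
```

prints

```
['Abdomen', 'Chest', 'Cloaca', 'Flanks', 'Throat']
 region channel  tree_clust       JND  pct_tot  pct_within  pct_males
Abdomen      dS           2 16.196932     31.0       100.0 100.000000
Abdomen      dL           2 25.336348     31.0       100.0 100.000000
  Chest      dS           2 16.247562     22.0       100.0  92.307692
  Chest      dL           2 48.008949     14.0       100.0  69.230769
```

The five regions flagged on the chromatic channel are exactly the
regions where the generator planted male-specific color patches
(orange/red venter, yellow cloaca, blue/green/yellow flanks). For the
Abdomen, the male-specific cluster at the 2-cluster cut holds 31 % of
the region's spectra, is 100 % male, and sits ≈16 JND from the rest of
the tree — far beyond the 2-JND discriminability threshold. The
`diversity_randomization.csv` report in `results/demo/` adds the
per-index permutation tests (males significantly exceed females in
color volume and span in the planted regions; females carry the higher
UV centroid on the venter).

The same stages are available from a shell:

```bash
dichroma simulate --scale 0.25 --seed 7 --outdir sim/
dichroma dichromatism sim/spectra.csv sim/metadata.csv --out table1.csv
dichroma run --scale 0.25 --n-perm 1000 --seed 7 --outdir results/demo
```

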