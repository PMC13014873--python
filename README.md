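# ramansen

Raman spectral analysis of autumnal leaf senescence, packaged as a tested,
reusable pipeline:

- **synthgen** — seeded synthetic data: six senescence classes (HOL,
  MinSOL-H, ModSOL-H, MinSOL, ModSOL, SOL) of Lorentzian-peak Raman spectra
  on a 690–1655 cm⁻¹ grid with class-dependent fluorescence intensity
  scaling, smooth baselines, Gaussian noise and cosmic-ray spikes; plus
  single-wavelength absorbance draws and RGB leaf patches.
- **prep** — dataset IO (long TSV / per-spectrum CSV), width-based
  cosmic-ray removal, iterative restrained polynomial baseline subtraction
  (order 11, noise tolerance 1.5), range truncation, 1003 cm⁻¹
  normalisation.
- **analytics** — peak intensities and ratio sets (700/1147, 898/1606,
  1003/1525, 1226/1456), the cellulose crystallinity index
  X_c = I₁₄₈₁/(I₁₄₆₂+I₁₄₈₁), Simpson's-rule region areas and relative
  areas, linear/exponential trend fits with R², RGB channel means, and
  instrument utilities (diffraction-limited spot size, total integration
  time).
- **stats** — tie-corrected Kruskal–Wallis, Dunn's post-hoc pairwise z
  tests (none/Bonferroni/Holm adjustment), significance labels
  (ns / * / ** / *** at 0.05 / 0.01 / 0.005).
- **som** — online Kohonen self-organising maps on a hexagonal grid with
  majority-class neuron labelling, confusion-matrix evaluation, stratified
  80/20 split + 10-fold CV with repeated runs, and per-class discriminant
  (SOMDI) profiles including class-subset refits.
- **multivariate** — PLS-DA (NIPALS PLS2 on autoscaled features vs one-hot
  labels) with R²/Q²/VIP, PCA + Lloyd k-means on the first two components,
  and a bagged random forest with OOB error, OOB permutation importance,
  proximity matrices and within-class outlier scores.
- **catabolite** — chlorophyll-catabolite vibrational line lists: JSON
  parsing, the top-5 / activity ≥ 30 filter, stage tallies, Lorentzian
  broadening, spatially-unique band grouping and matching against per-class
  experimental peak tables. Packaged transcriptions of the band-assignment
  and filtered-peak tables ship under `ramansen/data/`.
- **pipeline / cli** — end-to-end orchestration with config hashing and
  stage resumability.

## CLI

```sh
ramansen simulate --n-per-class 100 --seed 1 --out out/
ramansen prep --input out/dataset.tsv --output out/pre.tsv \
    --cosmic-width 2 --baseline-order 11 --noise-tolerance 1.5
ramansen analyze crystallinity --input out/pre.tsv --output out/xc.tsv
ramansen stats kw-dunn --input out/xc.tsv --by class --value crystallinity \
    --output out/xc_kw.tsv
ramansen som train --input out/pre.tsv --model-out out/som.json
ramansen mva rf --input out/pre.tsv
ramansen catabolite match --output out/match.tsv
ramansen run-all --out out/full --seed 7          # everything in one go
```

`run-all` writes preprocessed data, analytics and statistics tables, SOM and
multivariate reports, the catabolite match report and a JSON + Markdown
summary, each stage stamped with the config hash so unchanged reruns skip
completed stages.

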