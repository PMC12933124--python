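# Methods

## The problem

Cellular cryo-electron tomography (cryo-ET) images a vitrified cell through a
thin lamella — a ~0.18 µm slab milled out of the frozen sample — so any one
experiment sees only a sliver of the cell. Which freezing method
(plunge freezing vs. high-pressure freezing, HPF), which sectioning method
(none, on-grid FIB-SEM, plasma-FIB, cryo-ultramicrotome, cryo-FIB lift-out,
serial lift-out) and how much material each combination yields are empirical
questions answered by surveying the literature. This package models that
survey quantitatively: a validated per-imaging-event table, closed-form yield
equations, a rule-based preparation planner, rank statistics across domains
of life, and a biodiversity-coverage census.

## The yield model

For a cell of maximal recorded dimension `L` (µm) and a sectioning method
producing `Nl` lamellae of width `l` per workflow pass, the percent of the
cell captured is

```
P = 100 · l · Nl / L        (capped at 100)
```

`Nl = 1` for single-lamella methods (FIB-SEM, plasma-FIB, single lift-out);
serial methods stack sections along `L` at a method separation `s`, so
`Nl = max(1, ⌊L/s⌋)`. Defaults: `l = 0.18` µm, `s = 4` µm for serial
lift-out (sub-4 µm sections exist; the separation is configurable),
`s = 0.18` µm — contiguous slices — for the ultramicrotome. The floor is
clamped at 1 because a cell the method can reach yields at least one
lamella; the cap at 100% exists because contiguous ultramicrotome slices on
a cell whose length is not a multiple of the slice width would otherwise
exceed full coverage.

Cells per lamella and time to expose `n` cells:

```
Nc   = Al / Ac
Tnc  = Tl · n / Nc
```

where `Al` is the lamella cross-sectional area, `Tl` the per-lamella milling
time (trenching and lift-out included) and `Ac` the cell cross-sectional
area, approximated as a sphere of diameter equal to the maximal dimension:
`Ac = π (L/2)²`. The maximal dimension is used because it reproduces the
four standard benchmark areas from the recorded cell sizes
(E. coli 2 µm², S. cerevisiae 19.6 µm², C. reinhardtii 50.3 µm²,
HeLa 227.0 µm²). Shape-specific volume models are deliberately absent:
lamella volumes often exceed entire prokaryotic cell volumes, which makes
volume fractions unstable across domains, so shape classes are metadata.

Benchmark workflow constants (all configurable via YAML):

| workflow | Al (µm²) | Tl (min) |
|---|---|---|
| plunge + FIB-SEM | 100 (50 for bacterial biofilm) | 60 |
| HPF + Waffle | 400 | 150 |
| HPF + serial lift-out | 250 | 75 |

Tomograms per lamella divide `Al` by a typical illumination area
`π·2² = 4π ≈ 12.6` µm² (a 1.8 × 1.8 µm tomogram at 4.4 Å/pixel), rounded to
the nearest integer — giving 32 (Waffle), 20 (serial lift-out) and
8 (plunge + FIB-SEM).

### Display conventions

Percent splits and tomogram counts round half away from zero (matching the
familiar 65/26/8/1 sectioning split and 31.8 → 32). `Nc` is displayed to the
nearest integer when ≥ 1 and to the nearest 0.5 below 1 (a lamella smaller
than one cell still captures a meaningful fraction; 100/227 → "0.5"). Full
precision is retained internally everywhere.

## The preparation planner

`recommend_workflow` encodes the empirical size transitions as deterministic
half-open `[low, high)` rules on the smallest (thickness) and largest (L)
recorded dimensions:

* thickness ≤ 1 µm — plunge freeze, image intact;
* L < 100 µm — plunge freeze + FIB milling (gallium FIB-SEM below 10 µm
  thickness, plasma-FIB/Waffle above);
* 100 ≤ L < 200 µm — HPF + cryo-FIB lift-out;
* L ≥ 200 µm — HPF + serial lift-out with cryoprotectant (required; a
  warning is attached when none is available).

The no-sectioning threshold is a design choice in genuinely ambiguous
territory: TEM image formation wants ≤ 0.3–0.5 µm of material, yet the
literature census shows most bacteria (~1 µm thick, in 1–10 µm plunge ice)
imaged intact — 65% of entries are unsectioned and predominantly bacterial.
The default of 1.0 µm follows that observed practice; users modelling a
strict electron-transparency budget can set 0.3 µm in the thresholds
config. All four boundaries ship in `data/defaults.yaml`.

## Statistics

Per-domain percent-imaged distributions are skewed, heavy-tailed and highly
unbalanced (hundreds of bacteria vs. ~a dozen archaea), so group comparison
is rank-based. Both tests are implemented from their formulas with midrank
ties:

* Kruskal–Wallis: `H = [12/(N(N+1))] Σ R²ᵢ/nᵢ − 3(N+1)`, divided by the tie
  correction `1 − Σ(t³−t)/(N³−N)`, referred to χ² with k−1 df. All-tied
  data returns H = 0, p = 1 rather than an error.
* Dunn's pairwise z:
  `z = (R̄ᵢ−R̄ⱼ) / sqrt([N(N+1)/12 − Σ(t³−t)/(12(N−1))](1/nᵢ+1/nⱼ))`,
  two-sided normal p, with optional Holm or Bonferroni adjustment. The
  default is no adjustment, which is the convention under which the field's
  published pairwise p-value magnitudes are reported.

p-values are floored at 1e-300 instead of underflowing to 0. The
size-landscape fit is ordinary least squares of width on length; both axes
are log10 by default because dimensions span four orders of magnitude
(0.1–2000 µm), with a raw-scale option exposed since either convention is
defensible for the R² summary.

## Biodiversity coverage

Distinct-taxon counts use full names at species/cell-line rank and
first-whitespace-token genera (cell lines never contribute genera; an
irregular name can be handled upstream by editing the table). Coverage gaps
are `log10(n_database / n_imaged)` and `100 · n_imaged / n_predicted`.
Database totals are configuration, not live queries — databases drift, and
pinned constants keep the analysis reproducible. The shipped
`data/richness_synthetic.yaml` is a synthetic stand-in (labelled as such)
constructed to sit in the empirically observed regimes: imaged diversity
2–3 orders below rRNA libraries, 4–5 orders below planetary predictions,
kingdom species coverage at 0.0001–0.02% with predicted totals split
89/3/7/1% across Animalia/Plantae/Fungi/Protista. Swap in real constants
via `--richness`.

## The synthetic census generator

`generate_entries` emulates the structure the analysis assumes, so every
stage is testable without external data. What it models:

* domain mix 164 : 14 : 188 (bacteria : archaea : eukaryotes), allocated by
  largest remainder so default counts are exact at n = 366;
* per-domain log-normal maximal dimensions, clipped to 10⁻¹–10³·³ µm, with
  medians 2.0 µm (bacteria), 18/14 ≈ 1.29 µm (archaea) and 18 µm
  (eukaryotes) — chosen so a single 0.18 µm lamella captures median 9%,
  14% and 1% of the cell respectively, the observed domain medians;
  dispersions 0.25/0.3/0.8 dex reflect that eukaryotic entries range from
  algae to tissue slabs while prokaryotes cluster tightly;
* domain-typical shapes (prokaryotes capsule/sphere; eukaryotes ≥ 100 µm
  become rectangular tissue slabs with a > 1 µm thickness);
* freezing/sectioning assigned by the planner with probability
  1 − `rule_noise` (default 0.1 — real studies deviate from the typical
  choice, e.g. plunge freezing large samples under cryoprotectant), else a
  uniformly random alternative;
* cryoprotectant exactly when the maximal dimension exceeds 200 µm;
* taxon names from fixed genus/epithet wordlists (with a 35% eukaryotic
  cell-line fraction) so distinct-counting paths see realistic duplication.

All draws come from one `numpy` Generator keyed by the seed; output is
deterministic per seed. What it does **not** model: publication-year
dynamics, citation metadata, genuine taxonomic composition, correlations
between shape and method beyond size, or curation noise in recorded
dimensions. Tests passing on synthetic data therefore validate the
machinery and the encoded size rules, not the field's actual census values;
checks that need the curated table live in an optional integration module
that activates when the table is present at `data/table_s1.csv`.

## Numerical choices and problem sizes

Structure-recovery checks bin sizes on a 0.1 dex log grid and use 4,000 to
6,000 generated entries, where the sampling error of a log-normal median is
well under the asserted 15% tolerance; oracle equivalence checks use 500
random small rank datasets and 1,000 random interval-packing cases. The
full suite runs in a few seconds on one CPU.

## Known limitations

* The planner is a size-only decision rule; composition effects (salt,
  vacuoles, exoskeletons, filaments) are out of scope by design.
* `P` measures coverage along one axis; it is not a volume fraction.
* The sphere approximation overestimates `Ac` for elongated cells, making
  `Nc` conservative for rod-shaped bacteria.
* Genus extraction is first-token only; taxonomy reconciliation (synonyms,
  renamed genera) is out of scope.
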