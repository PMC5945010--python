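# Methods

## The greenness index

The per-pixel green chromatic coordinate `G/(R+G+B)` is computed on 8-bit
sRGB values exactly as decoded — no gamma linearization, white balance or
exposure correction — and averaged over the image. Two conventions matter:

* **ratio-then-mean, not mean-then-ratio.** The index is the mean of the
  per-pixel ratio. The ratio of channel means is a different statistic
  (they coincide only when brightness and hue are independent), and the two
  must not be conflated.
* **black pixels are excluded, not imputed.** At `R=G=B=0` the ratio is
  undefined; such pixels are dropped from the mean and counted in
  `n_pixels_excluded` rather than assigned ⅓. An entirely black image is an
  error.

Grayscale inputs are expanded to `R=G=B` (index exactly ⅓); alpha channels
are dropped. How real pipelines handle non-RGB inputs varies; these are
this package's conventions and are covered by tests.

## Corpus cleaning

Two filters are applied, in a fixed order (size first, then duplicates —
with byte-identity the order cannot change the outcome, but fixing it makes
the removal log deterministic):

* **size**: files with fewer than `min_bytes` bytes are removed. The
  default is 10 240 (binary 10 kB, strict less-than); the threshold is
  configurable because the decimal reading (10 000) is equally defensible.
* **duplicates**: files with byte-identical content (SHA-256) are collapsed
  to the earliest-timestamped record, ties broken by the lexicographically
  smallest record id. Near-duplicate/perceptual hashing is deliberately out
  of scope: byte-identity matches spam-repost behaviour and is
  deterministic.

The `FilterReport` satisfies the accounting identity
`n_input = n_retained + n_duplicates + n_undersized + n_unreadable` and is
asserted on every run. Filtering is idempotent, and the retained *set* is
independent of input order.

Advertisement images are *not* filtered: they are visually valid images and
no content-based classification is attempted. They remain as a bias source,
which the synthetic generator reproduces deliberately.

## Bootstrap aggregation

All intervals are **percentile bootstrap**: the statistic is recomputed on
`n_reps` resamples drawn with replacement at the original sample size and
the (α/2, 1−α/2) empirical quantiles are reported. Defaults: `n_reps =
10 000`, `α = 0.05`. BCa or studentized intervals were considered and
rejected: the percentile method is the simplest member of the family, and
the method name is recorded in the output metadata so downstream users know
what they have. Known behaviour: at pool sizes below ~30 the percentile
interval undercovers slightly (≈93 % empirical at n = 20); the default
study sizes keep pools at 40+.

Pools are (park, month) across years, and (park, JJA/DJF) for seasons; DJF
pools month labels without year-shifting December (the analysis treats the
two-year window as one pool). Months with no data are absent from outputs,
never zero-filled. The coefficient of variation is the sample SD (ddof = 1)
divided by the mean; it is 0 for n = 1.

The summer−winter contrast resamples the two pools independently in each
replicate and bootstraps the difference of means. Significance means the
95 % percentile interval of the difference excludes zero; the weaker
visual criterion (the two seasons' own CIs not overlapping) is reported
alongside as `ci_overlap`. A sample of size 1 yields a degenerate interval
equal to the value, flagged. No multiple-testing correction is applied
across parks.

Randomness: one root seed; every (park, period) pool derives a child
generator from `SeedSequence([root, crc32(labels)])`, so results are
reproducible and independent of iteration order.

## NDVI comparison

"Within 0.5°" of a park centre is implemented as an inclusive Euclidean
radius in degree space (`sqrt(Δlat² + Δlon²) ≤ r + 1e−9`, the tolerance
absorbing float noise in lattice coordinates); a square box selection is
available as a config alternative since the phrase is ambiguous. Selected
cells are averaged per month with a plain arithmetic mean (no area
weighting: at these extents and a regular lattice the difference is
negligible, and the synthetic grid is exactly regular).

Correlation is computed on the **pooled** park-month pairs — per-park
correlations on 12 points are too unstable to be meaningful and are not
emitted. Pearson's r carries a percentile-bootstrap CI obtained by
resampling pairs (rows) with replacement; resamples with zero variance in
either series are dropped from the replicate distribution. Spearman's ρ is
a point estimate only. No regression slope is fitted: greenness and NDVI
are different physical quantities and their slope is not expected to be
near 1; the comparison is correlation-only.

## The synthetic generator

The generator encodes the structure the analysis assumes; it is a model,
not a re-creation of any real corpus.

* **Seasonal cycle**: true monthly mean greenness
  `mu(m) = base + A·cos(2π(m − peak)/12)` — the simplest smooth annual
  cycle. Default profiles place summer (JJA) means at ≈0.31–0.36 with
  winter 0.05–0.08 lower: Great Smoky Mountains greenest (summer > 0.36),
  Grand Canyon flat (A = 0, mean < 0.32, a desert park whose visitors
  photograph rock formations), Rocky Mountain the strongest cycle
  (A = 0.045). Peak month is July for all parks.
* **Image-level noise**: per-image target ~ Normal(mu(m), σ_img) with
  σ_img ≈ 0.030–0.034, chosen so the monthly coefficient of variation is on
  the order of 0.1 — the dispersion real crowdsourced corpora show from
  lighting, framing and off-topic content. The Gaussian is a convenience;
  real noise is heavier-tailed and asymmetric, so passing tests demonstrate
  correct *estimation machinery*, not robustness to real-world outliers.
* **Pixel construction**: every pixel uses a fixed channel sum S = 300 so
  one parameter controls the index exactly: `G = clip(round((target+ε)·S),
  0, 255)` with per-pixel ε ~ Normal(0, σ_px) (default 0.04), rounding half
  away from zero, and the remainder split R = ⌈(S−G)/2⌉, B = ⌊(S−G)/2⌋ (the
  odd byte to R). The *realized* index of the constructed pixels — computed
  by the same code the analysis uses — is stored as ground truth, so
  downstream agreement can be asserted to 1e−12 through a lossless PNG
  round trip. JPEG output is supported but not bit-pinned (decoder
  variability).
* **Posting volume**: summer-peaked monthly counts (July 60, winter 20 per
  park-month, before scaling), with an October bump for Great Smoky
  Mountains emulating autumn "leaf peepers". These are roughly 1/15 the
  magnitude of a real two-year corpus; the scale preserves the winter:summer
  imbalance that widens winter CIs while keeping a full run in seconds.
* **Contamination**: exact byte-duplicates (Binomial(n, 0.02) per
  park-month, copying a same-month file) and undersized files (tiny valid
  PNGs, Binomial(n, 0.01)), so the filter should remove ≈3 % in
  expectation; plus "advertisements" (rate 0.02, but 0.15 for Glacier)
  whose target is mu(peak month) regardless of posting month — the
  mechanism that flattens Glacier's observed cycle. Clean and ad PNGs are
  padded above the 10 kB threshold with an ancillary `tEXt` chunk (pixel
  data untouched) so the size filter removes exactly the injected
  undersized class. Timestamps are ISO dates with day = 15; only the month
  label is consumed.
* **NDVI grid**: per cell and month,
  `clip(intercept + slope·mu(m) + Normal(0, σ_cell), −1, 1)` on a regular
  lattice (default 0.1° step over 1°, i.e. 121 cells, 81 within the 0.5°
  radius). Defaults intercept 0.2, slope 1, σ_cell 0.27. The cell noise is
  deliberately large: it stands for the mismatch between a satellite
  footprint and the scenes people photograph, and is set so the closed-form
  attenuated correlation of the default scenario,

  `r = s·var(mu) / sqrt((var(mu) + mean σ_img²/n_img)·(s²·var(mu) + σ_cell²/n_cells))`,

  is ≈ 0.6 — the magnitude at which such comparisons typically land. This
  formula (implemented as `synth.attenuated_correlation`) is the oracle the
  correlation-recovery tests check the pipeline against.

`sample_observations` provides a pixel-free fast path drawing greenness
values directly from the statistical model; it is used for repeated-run
studies (power, type-I error, CI coverage) where encoding images would add
nothing.

## Numerical and design choices

* Exactness targets: vectorized index vs naive per-pixel loop ≤ 1e−12;
  realized synthetic greenness vs analysis recomputation ≤ 1e−12 (PNG).
* Degenerate inputs: constant samples give zero-width intervals; n = 1
  pools are flagged degenerate; empty pools are absent with a warning, not
  zeros; all-black images and zero-variance correlation series are errors.
* The bootstrap index matrix is chunked to bound memory at tens of MB
  regardless of `n_reps`.
* End-to-end determinism: a rerun with the same seed reproduces every
  output byte-for-byte; every analysis run writes a JSON manifest with the
  seed, a config hash and package versions.
* Study sizes used by the shipped statistical tests: the default scenario
  (~7 000 images, 96 park-month pools), 1 000 Gaussian trials at n = 100
  for interval coverage, 30 seeded runs for contrast power, 400 label
  permutations for the false-positive rate.

## Limitations

* The generator's Gaussian, cosine-cycle world contains no lighting drift,
  image filters, off-topic photos beyond the mean-shifted "ads", or
  spatially structured NDVI error; recovery results bound estimator
  correctness, not field performance.
* Byte-identity misses re-encoded duplicates; a perceptual-hash stage would
  be needed for those.
* No phenophase-date extraction (green-up/senescence timing), smoothing, or
  gap-filling of monthly series; the outputs are the monthly/seasonal
  tables themselves.
* Park "centres" are single coordinates; real parks are extended and
  irregular, and the 0.5° disc is a crude footprint.
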