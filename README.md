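# ambientgreen

Vegetation phenology from *ambient* image corpora — large collections of
photographs (e.g. social-media posts tagged with a national park's name)
taken with no scientific intent, which nonetheless carry a seasonal
vegetation signal. The package computes a per-image greenness index,
cleans the corpus, aggregates park-level monthly and seasonal cycles with
bootstrap confidence intervals, and compares the cycles against a gridded
monthly NDVI product. It is aimed at researchers exploring crowdsourced or
phenocam-style RGB imagery as a phenology proxy.

Because real social-media corpora are not redistributable, the package
ships a first-class synthetic-data generator that emulates their
statistical structure (seasonal greenness cycles, summer-peaked posting
volume, duplicate/undersized contamination, off-season advertisement
images, and a coupled NDVI grid) with a full ground-truth table, so every
stage is testable offline.

## The method

For a pixel with 8-bit channels (R, G, B), the green chromatic coordinate
is

```
gcc = G / (R + G + B)
```

and an image's **greenness index** is the arithmetic mean of `gcc` over all
pixels with a positive channel sum (pure black pixels are excluded; the
ratio is undefined there). The index is ⅓ for any achromatic image and
rises as foliage greens up.

The analysis chain:

1. **Filter** — remove files smaller than 10 kB (10 240 bytes) and all but
   the earliest copy of each set of byte-identical files.
2. **Index** — compute the greenness index per image.
3. **Aggregate** — pool observations by (park, calendar month) and by
   season (JJA = June–August, DJF = December–February); report the mean, a
   percentile-bootstrap 95 % CI of the mean (10 000 resamples with
   replacement at the original sample size), the sample size and the
   coefficient of variation. The summer−winter contrast bootstraps the
   difference of means with independent resampling of the two pools.
4. **Compare** — select NDVI grid cells within 0.5° (Euclidean in degree
   space, inclusive) of each park centre, average them monthly, pair with
   the park's monthly greenness means, and compute pooled Pearson (with
   bootstrap CI) and Spearman correlations across all park-months.

## Worked example

```
$ ambientgreen simulate --out demo --seed 1
wrote 7073 records for 8 parks to demo

$ cat > demo/config.yaml <<EOF
manifest: demo/manifest.csv
image_root: demo
ndvi_grid: demo/ndvi.csv
park_centers: demo/centers.csv
out_dir: demo/analysis
seed: 2
n_reps: 10000
EOF

$ ambientgreen analyze --config demo/config.yaml
retained 6856/7073 records (3.1% removed); outputs in demo/analysis

$ ambientgreen report --out demo/analysis
```

The report shows, per park, the summer and winter pooled means with their
bootstrap CIs, e.g.

```
| park           | JJA mean [95% CI]            | DJF mean [95% CI]            | diff   | significant |
| Grand Canyon   | 0.307 [0.304, 0.311] (n=336) | 0.309 [0.304, 0.314] (n=120) | -0.002 | no          |
| Rocky Mountain | 0.350 [0.346, 0.354] (n=336) | 0.274 [0.267, 0.281] (n=120) | +0.076 | yes         |
...
Pearson r = 0.67 (95% CI 0.56 to 0.77); Spearman rho = 0.66; n = 96 park-month pairs.
```

Reading this: 3.1 % of the simulated corpus was contamination (duplicates
and undersized files) and was removed; seven of the eight parks show a
summer greenness significantly above winter at the 95 % level, while the
flat desert park (Grand Canyon) does not; and the park-month greenness
means correlate positively (r ≈ 0.6–0.7) with the NDVI-like satellite
series, attenuated below 1 by image-level and cell-level noise exactly as
the generative model predicts.

The same chain is available as library functions
(`ambientgreen.filter_corpus`, `corpus_greenness`, `monthly_stats`,
`seasonal_stats`, `season_contrast`, `select_park_cells`, `correlate`, …)
operating on pandas DataFrames.

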