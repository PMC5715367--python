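# phenoplate

High-throughput, plate-based phenotyping of *Arabidopsis thaliana* seedlings
under abiotic stress, as a tested and reusable Python pipeline.

The package is aimed at plant phenomics groups screening T-DNA insertion
mutant collections with plate imaging robots (visible-light and chlorophyll
fluorescence cameras). It covers the full path from raw plate photographs to
gene-level candidate lists:

1. **Assay-specific segmentation** (`phenoplate.imgproc`, `phenoplate.assays`)
   — rule-based foreground masks in RGB/HSB color space, adaptive local-mean
   thresholding for backlit root images, connected-component labeling with
   Moore contour tracing, and removal of embossed plate-grid artifacts.
   Four assays are built in, each with its published pixel and object rules:
   * **salt** (survival): VIS saturation S > 49 under stress (S > 74 under
     standard growth) with a gray-band filter keeping gray ∈ [0,140] ∪
     [150,255]; FLUO S > 20; objects with area > 40 px within 130 px of the
     grid-cell center.
   * **arsenic** (germination): VIS R < 254, G < 246, B < 254 on a backlit
     near-white field; FLUO S > 50.
   * **freezing** (leaf damage): B < 127 and (R − B)/(R + B) > 0.20;
     seedling objects with area ∈ (10 000, 40 000) px.
   * **phosphate** (root elongation): mean auto-local threshold, grid-line
     removal (horizontal runs > 50 px, vertical > 240 px), root objects
     (area > 109 px, circularity < 0.70) merged with shoot objects
     (23 < Bri < 138) into one digital plant per seedling.
2. **Morpho-colorimetric profiling** (`phenoplate.plants`) — per digital
   plant: area *A*, contour perimeter *P* (axis steps 1, diagonals √2),
   circularity 4π*A*/*P*², compactness *A*/*P*, equivalent-ellipse major and
   minor axes from second central moments, eccentricity, the modal gray
   intensity (hisgreypeak), K-class hue histograms (K = 16 per modality,
   joined VIS+FLUO vectors; K = 32 for freezing), and the yellowish damage
   index (hue ∈ [0, 40), damaged if > 50 % of pixels).
3. **Screen statistics** (`phenoplate.screen`) — hierarchical two-group
   clustering of joined color profiles to call alive/dead (germinated/seed);
   per-line Fisher's exact tests on 2×2 line × group tables (one-way ANOVA
   on the major axis for phosphate); Benjamini–Hochberg FDR across lines
   with the significance rule p_adj < 0.05; and the multi-trait C1–C5
   clustering with per-line density heatmaps.
4. **Gene triage** (`phenoplate.triage`) — evidence categories 1–6 from the
   per-line results, the stringent two-part filter (≥ 2 lines significant in
   the same stress **and** minimum p_adj < 0.01 within that stress), the
   multi-stress count, and the two report tables. The per-line adjusted
   p-values of the published exapted-transposable-element (ETE) screen are
   bundled as plain CSV for the worked examples.
5. **Synthetic ground truth** (`phenoplate.simulate`) — a deterministic
   generator for all four plate formats with per-line effect parameters
   (survival/germination probability, damage fraction, root-length shift),
   so every stage is testable against known truth without any image
   downloads.

## Worked example

Gene-level triage on the bundled screen tables:

```python
>>> from phenoplate import triage
>>> results, meta = triage.load_reported_screen()
>>> genes = triage.summarize_genes(results, meta)
>>> sum(g.stringent_pass for g in genes)
25
>>> two_line = results[results.locus.isin(meta.loc[~meta.single_line, "locus"])]
>>> triage.multi_stress_count(two_line)
12
```

25 genes pass the stringent filter and 12 of the multi-allele genes carry a
p_adj < 0.01 line in two or more stress conditions.

A line-vs-wild-type survival test at the screen's design size (36 seedlings
× 3 replicates, survival probability 0.15 vs 0.65):

```python
>>> from phenoplate import screen, simulate
>>> counts = simulate.simulate_survival_counts(
...     {"Col-0": 0.65, "mutant": 0.15}, n_per_line=108, seed=1)
>>> screen.line_significance(counts, test="fisher")
     line  statistic         p_raw         p_adj  significant
0  mutant    0.06843  2.897826e-17  2.897826e-17         True
```

The mutant is flagged with an odds ratio of 0.068 (strongly reduced
survival) at an FDR-adjusted p far below 0.05.

The same flow works end to end from images via the CLI:

```bash
phenoplate simulate --assay salt --seed 1 --out sim/
phenoplate segment  --assay salt --vis sim/ --layout sim/layout.yaml \
                    --manifest sim/manifest.csv --out records.csv
phenoplate stats    --records records.csv --assay salt --out results.csv
phenoplate triage   --reported --out summary.csv
```

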