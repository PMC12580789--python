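# cinsig — chromosomal-instability signatures and tumor subtyping

High-grade serous ovarian carcinoma (HGSC) genomes are shaped by pervasive
chromosomal instability: deletions, duplications, translocations, focal
amplification, whole-genome doubling. `cinsig` implements an end-to-end
analysis that turns per-sample copy-number segments and structural-variant
(SV) junctions into molecular subtypes with clinical associations:

1. **Feature quantification** — 44 counts per sample across 10 families:
   SV event classes from single-linkage junction clustering (simple,
   complex, intra/inter-chromosomal, compact/sparse, deletion and
   duplication length bins, insertions, reciprocal events, unbalanced
   translocations, LINE insertions, chromothripsis-like chromosomes) and
   copy-number families (deletion/duplication magnitude — the 20th/80th
   length-weighted percentile of log(cn/ploidy) — segment size,
   changepoints, segments per 5 Mb and per chromosome arm, oscillation
   chains).
2. **Discretization** — continuous families are binned with models fitted
   once on the extraction cohort: exact Fisher–Jenks natural breaks, or a
   BIC-selected 1-D Gaussian mixture for segments-per-5Mb.
3. **Signature extraction** — the count matrix V (samples × 44) is modeled
   as V ≈ H·Wᵀ with nonnegative signature profiles W (columns sum to 1) and
   activities H, fitted by multiplicative-update NMF under generalized
   Kullback–Leibler divergence. The rank is chosen by bootstrap stability:
   Poisson-resample V, factorize each resample, pool the signature columns,
   cluster them by cosine k-medoids, and keep the largest rank whose least
   reproducible signature still clusters with silhouette ≥ 0.8.
4. **Assignment** — per-sample nonnegative least squares on W with backward
   pruning of signatures that barely change the reconstruction.
5. **Subtyping** — Monti consensus clustering (subsample, average-linkage
   under 1 − Pearson distance, co-clustering frequencies) on exposure
   fractions; patient-level stability (all of a patient's samples in one
   cluster); a random-forest validation classifier.
6. **Survival statistics** — Kaplan–Meier curves, the multi-group log-rank
   test, Harrell's concordance index (all first-class implementations),
   Mann–Whitney enrichment with Benjamini–Hochberg correction, and Cox
   proportional hazards via lifelines.

Real HGSC whole-genome data are controlled-access, so the package ships a
**synthetic-cohort generator**: six mutational-process templates
(BRCA1-like, BRCA2-like, tandem-duplicator, focal amplifier, WGD-rearranged,
simple genome) whose mixtures produce junction–segment-concordant genomes
with known exposures, purity/ploidy metadata, and subtype-linked survival.
Every stage is therefore testable against ground truth.

## Worked example

The numbered scripts under `analysis/` run the study on a simulated
40-patient cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py 11
python analysis/02_quantify_features.py 11
python analysis/03_extract_signatures.py 11
python analysis/04_cluster_subtypes.py 11
python analysis/05_survival_analysis.py 11
```

Output from a run with seed 11:

```
cohort: 71 samples / 40 patients, 17353 segments, 6663 junctions
junction-segment concordance violations: 0
71 samples -> 62 above purity 0.20, 54 selected for extraction (highest purity per patient x tissue area)
feature matrix: 62 samples x 44 features, median row total 935 counts
selected rank 6 (per-rank min-signature stability: {2: 1.0, 3: 1.0, 4: 0.99, 5: 0.74, 6: 0.85, 7: 0.38, 8: 0.07})
  SCN-B: best-matching process BRCA1like (Spearman rho 0.88)
  SCN-C: best-matching process WGDRearranged (Spearman rho 0.85)
  SCN-D: best-matching process TandemDup (Spearman rho 0.86)
  SCN-F: best-matching process BRCA2like (Spearman rho 0.87)
consensus clustering chose k=5; 90% of patients have all samples in one cluster
random-forest validation classifier: OOB accuracy 0.92
log-rank across 4 subtypes (33 stable patients): chi2=1.12, p=0.772
```

Reading this: six stable signatures were extracted de novo (the
min-signature stability collapses past rank 6), four of them map cleanly
onto planted generator processes (Spearman ρ ≥ 0.85 against true
exposures), 90% of multi-sample patients cluster consistently, and the
subtype classifier reproduces the labels with 0.92 out-of-bag accuracy. The
log-rank p on this small cohort is not significant — 33 stable patients
across four groups carry little power against the generator's moderate
hazard contrasts.

The same stages are scriptable via the `cinsig` CLI (`simulate`, `run`,
`extract`, `assign`, `cluster`).

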