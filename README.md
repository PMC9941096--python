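# lipid4d

A toolkit for 4D lipidomics data in which every detected ion carries four
descriptors: m/z (Da), retention time (min), collision cross section (Å²),
and an optional MS/MS spectrum. It operates entirely on plain-text feature
tables — no vendor raw formats — and covers:

- **Feature selection** (`lipid4d.pipeline`): greedy 4D alignment of
  replicate runs into a bucket table, recursive gap-filling at a lowered
  detection threshold, two-threshold presence filtering, solvent-blank
  background subtraction, cross-experiment overlap matching, and a dilution
  response filter (Pearson r ≥ 0.9 on per-level means, SD of max-normalized
  means > 0.1).
- **Library building and annotation** (`lipid4d.library`,
  `lipid4d.annotation`): replicate-averaged 4D reference entries, and banded
  confidence scoring per dimension (mass 1–3 ppm, RT 0.1–0.5 min,
  CCS 0.2–1.5 Å², MS/MS 900–500 on a fit / reverse-fit / purity composite),
  with tiers `full_4D` / `no_MS2` / `rejected`.
- **Quantification** (`lipid4d.quant`): multi-point power-law calibration
  (areaRatio = c1·concRatio^(1/c2), fitted in log–log space), one-point
  quantification, ng/mL → nmol/mL conversion via extraction volumes and
  adduct mass, LLOD/LLOQ (3.3·σ/s and 10·σ/s), recovery / matrix-effect
  arithmetic, CV, and batch-layout validation.
- **Blood-matrix statistics** (`lipid4d.stats`): pairwise Wilcoxon
  signed-rank dissimilarity counts with Benjamini–Hochberg correction,
  Friedman time-point tests, person-held-out random-forest classification
  with AUROC, PCA scores, pooled per-class SD, and ceramide/PC marker
  ratios.
- **Synthetic data** (`lipid4d.simulate`): fully seeded generators for
  libraries, replicate runs with background and dropout, dilution ladders,
  calibration series, and multi-matrix studies — each with exported ground
  truth so every downstream stage can be scored.

## CLI

The `lipid4d` entry point exposes one subcommand per stage:

```sh
# synthetic inputs with ground truth
lipid4d simulate library --seed 1 --out sim/
lipid4d simulate runs --seed 1 --n-replicates 32 --out sim/runs/

# feature selection chain
lipid4d align sim/runs/run*.tsv --out work/aligned
lipid4d filter-presence work/aligned --t-seed 17 --t-final 32 --out work/present
lipid4d subtract-blank work/present --blank blank.tsv --out work/clean
lipid4d filter-dilution work/clean --design sim/dilution/design.tsv --out work/final

# annotation and quantification
lipid4d annotate work/final --library sim/library.tsv --spectra sim/library.msp --out work/annotated
lipid4d quantify --calibration cal.tsv --samples samples.tsv --out quant.tsv

# statistics battery
lipid4d phenomap --concentrations conc.tsv --design design.tsv --out pheno/

# chained pipeline with a JSON manifest (funnel counts per stage)
lipid4d run --config pipeline.yaml --out run1/
```

Feature tables are TSV/CSV with columns `mz, rt, ccs, area` (optional
`spectrum_id`, `sample_id`); spectra are MSP (read/write) or MGF (read);
analyte lists and study designs are TSV. Bucket tables round-trip as a
`values` / `provenance` / `buckets` TSV trio.

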