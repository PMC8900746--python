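# mcanary

Screening for occult maternal malignancy from NIPT shallow cfDNA
sequencing, as a tested Python library + CLI:

- **z-score engine** — per-chromosome z-scores from binned fragment
  fractions against a reference panel, and the multiple-chromosomal-
  aneuploidy (MCA) flag (≥2 chromosomes with |z| > 3).
- **MTOP5Zscores predictor** — mean of the five largest absolute
  chromosome z-scores excluding chrY and chr19, with a strict cutoff call
  (default 5.94).
- **TSS / NPCC pipeline** — strand-aware 5′-end adjustment, 167-bp
  extension with a central 61-bp core window, per-100-kb copy-ratio
  normalization, per-gene RDPKM around TSS ± 1 kb, gene filtering
  (RDPKM < 100, log2 mean FPKM < 0.1), and normalized Pearson correlation
  coefficients (NPCC) against per-cancer-type expression references.
- **PTM panel** — the any-marker-above-cutoff plasma tumor marker rule.
- **tissue classifier** — 32-feature random forest (3 NPCC + 22 autosome
  z-scores + 7 PTMs; ntree=500, mtry=5) with deterministic leave-one-out
  cross-validation, per-class ROC/AUC, and Gini feature importances.
- **evaluation** — confusion matrices, sensitivity/specificity/PPV/NPV
  with exact Clopper–Pearson 95% CIs, ROC/AUC (tie-aware, equal to the
  normalized Mann–Whitney U), and Youden-optimal cutoff selection.
- **synthetic cohort** — seeded generators for every pipeline input:
  z-score cohorts with per-cancer-type chromosome amplification/deletion
  frequencies, the chr19 technical artifact in non-cancer samples, PTM
  panels calibrated near the published operating point, expression
  references, and fragment sets whose TSS coverage is anticorrelated with
  tissue expression (with optional embedded CNV segments).

## CLI

```sh
mcanary simulate --seed 3 --out cohort/          # synthetic inputs
mcanary zscore   --fragments x.bed --panel panel.tsv --out z.tsv
mcanary mtop5    --zscores cohort/zscores.tsv --out mtop5.tsv
mcanary npcc     --fragments cohort/fragments.bed --tss cohort/tss.tsv \
                 --expr cohort/expression.tsv --out npcc.json
mcanary classify --features features.tsv --loocv --seed 1 --out pred.tsv
mcanary evaluate --pred pred.tsv --truth cohort/truth.tsv --out metrics.json
```

Global options `--config cfg.yaml` and `--log-level` sit on the group;
all thresholds and window parameters live in `PipelineConfig`
(`mcanary.io_formats`) and default to the published operating values.

## Conventions

All internal coordinates are 0-based half-open; SAM input (1-based) is
converted at the boundary. Strand is mandatory on fragment input because
the 5′-end adjustment is strand-aware. All simulation is reproducible
under a fixed seed.
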