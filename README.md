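# metabosub

Metabolic subtyping of tumor cohorts from glycolytic and cholesterol-biosynthesis
gene expression.

The pipeline classifies each tumor sample into one of four metabolic subtypes
— **quiescent**, **glycolytic**, **cholesterogenic**, **mixed** — from the
median centered expression of two co-expressed gene cores:

1. **Preprocess** — TPM / log10(TPM+1) transform, tumor-purity filter
   (< 30% removed), gene-wise median centering and SD scaling.
2. **Consensus clustering** — resampled (reps=100, pItem=0.8, pFeature=1)
   Ward/Euclidean hierarchical clustering of the glycolysis (n=29) and
   cholesterol-biosynthesis (n=24) gene sets at k=4, with CDF / delta-area
   diagnostics.
3. **Core selection** — per gene set, the cluster with ≥ 50% members from
   that set; the most homogeneous candidate wins.
4. **Subtype assignment** — quadrant rule on per-sample median core
   expression: both scores ≤ 0 → quiescent; glycolytic > 0 only →
   glycolytic; cholesterogenic > 0 only → cholesterogenic; both > 0 → mixed.
5. **Survival** — Kaplan–Meier curves, k-group log-rank test, OS < 1 month
   exclusion, maximally selected cutpoint search.
6. **Mutation analysis** — CNV calls from integer copy status (≥ 3 amplified,
   ≤ 1 deleted) or SEG segments (≥ 10 probes, |seg mean| > 0.2), binary
   alteration matrices, per-gene 2×k subtype contingency tests with BH
   correction.
7. **IHC scoring** — immunoreactive score (proportion 0–4 × intensity 0–3)
   with negative/mild/moderate/strong bins.
8. **Pan-cancer screen** — the same loop per cohort with a ≥ 100-sample gate
   and a ≥ 75% core-homogeneity gate.

A synthetic-cohort generator (`metabosub.synthetic_data`) plants subtype
blocks, survival hazards and mutation frequencies so the full pipeline is
testable without any downloads.

## CLI

```bash
# generate a synthetic cohort
metabosub simulate --n-samples 480 --seed 7 --out cohort/

# full pipeline on any cohort directory
metabosub run-all --expr cohort/expr.tsv --clinical cohort/clinical.tsv \
    --gmt cohort/sets.gmt --maf cohort/mutations.maf \
    --seg cohort/segments.seg --bed cohort/genes.bed --out artifacts/

# individual stages
metabosub preprocess --expr expr.tsv --clinical clinical.tsv --out centered.tsv
metabosub cluster --expr centered.tsv --genes sets.gmt --k 2,3,4,5 --reps 100 \
    --p-item 0.8 --seed 17 --out consensus/
metabosub subtype --expr centered.tsv --labels consensus/labels_k4.tsv \
    --gmt sets.gmt --out subtypes.tsv
metabosub survival --clinical clinical.tsv --groups subtypes.tsv --out km
metabosub mutations --maf m.maf --seg s.seg --bed genes.bed \
    --subtypes subtypes.tsv --out mut
metabosub irs --in ihc.tsv --out irs.tsv
metabosub pan-cancer --root cohorts/ --gmt sets.gmt --out screen.tsv
```

All outputs are TSV; `run-all` additionally writes a JSON manifest (seed,
config hash, versions) and is byte-identical under a fixed seed and config.

## Layout

- `src/metabosub/data_io.py` — GMT / expression TSV / clinical TSV / MAF /
  SEG / BED readers and writers, domain types.
- `src/metabosub/synthetic_data.py` — planted-structure cohort generator.
- `src/metabosub/preprocess.py` — log transform, purity filter, DE gene
  selection, centering/scaling.
- `src/metabosub/consensus.py` — resampled consensus clustering + CDF
  diagnostics.
- `src/metabosub/subtyping.py` — core-cluster selection, pathway scores,
  quadrant rule, cross-tabulation.
- `src/metabosub/survival.py` — Kaplan–Meier, log-rank, cutpoint search.
- `src/metabosub/mutation.py` — CNV calling, alteration matrices,
  contingency tests.
- `src/metabosub/ihc.py` — immunoreactive score.
- `src/metabosub/pan_cancer.py` — per-cohort screening loop.
- `src/metabosub/pipeline.py`, `cli.py`, `config.py` — orchestration.
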