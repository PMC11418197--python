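# v2gmap

Variant-to-gene (V2G) mapping through open chromatin and Hi-C promoter
contacts, as a tested, reusable pipeline:

- **GWAS credible sets** — two-sided p-values → z-scores → approximate Bayes
  factors (Wakefield-style or `exp(z²/2)`) → posterior probabilities; the 95%
  credible set is the minimal descending-posterior prefix reaching the
  coverage target, then constrained to variants in accessible open-chromatin
  regions (OCRs).
- **Loop consensus** — multi-resolution (1/2/4 kb) loop calls are merged
  fine-to-coarse with a both-anchor-overlap rule (the highest resolution
  representative always wins), unioned across activation stages with
  per-stage support flags, and annotated into OCR ↔ gene-promoter contacts
  using strand-aware −1500/+500 bp promoter windows.
- **Effector-gene nomination** — accessible credible-set variants are linked
  to genes through promoter-proxy evidence (variant in an OCR overlapping a
  promoter window) and distal-contact evidence (variant in an OCR at a loop
  anchor whose partner anchor touches a promoter window), with descriptive
  statistics (genes per variant, TSS distances, nearest-gene classes,
  stage-sharing tiers, dynamic-gene subsetting).
- **Benchmarking** — precision/recall against truth gene sets, set
  concordance, a permutation null (random genes within 1 Mb of each
  sentinel), a one-sided continuity-corrected two-proportion test, and
  Benjamini–Hochberg adjustment.
- **Expression dynamics** — elbow-selected k-means clustering of expression
  trajectories with per-gene centroid correlations, and an immune
  expression-specificity score (whole blood + spleen over other tissues).
- **Synthetic fixtures** — a planted-ground-truth generator
  (`v2gmap.synthetic_data`) that emits every file dialect the pipeline
  reads, with causal variants, loops, effector genes, designed
  precision/recall truth sets, and five planted expression archetypes, all
  recoverable by construction.

All coordinates are 0-based half-open internally (BED native; GTF and
summary-statistic positions converted on read/write).

## CLI

```sh
v2gmap simulate --seed 7 --out fixture/          # planted synthetic fixture
v2gmap credset --sumstats fixture/sumstats.tsv --ocr fixture/ocrs.bed --out cs.tsv
v2gmap contacts --loops fixture/loops.bedpe --genes fixture/genes.tsv \
    --ocr fixture/ocrs.bed --out contacts.tsv
v2gmap v2g --sumstats fixture/sumstats.tsv --ocr fixture/ocrs.bed \
    --loops fixture/loops.bedpe --genes fixture/genes.tsv \
    --out pairs.tsv --summary-out summary.json
v2gmap benchmark --pred pairs.tsv --truth fixture/truth_genes.txt
v2gmap enrich --pairs pairs.tsv --compare eqtl_pairs.tsv \
    --genes fixture/genes.tsv --window 1000000 --iters 10000 --seed 7
v2gmap cluster --expr fixture/expression.tsv --k-range 2:9 --seed 7 --out clusters.tsv
v2gmap specificity --tissues gtex_medians.tsv --out spec.tsv
v2gmap validate fixture/ocrs.bed --kind ocr
```

## Python API

```python
from v2gmap import SimConfig, run_pipeline
from v2gmap.synthetic_data import simulate_fixture

fx = simulate_fixture(SimConfig(seed=7))
result = run_pipeline(fx.records, fx.ocrs, fx.loops, fx.genes,
                      chrom_length=fx.config.chrom_length)
pairs = result.pairs  # nominated variant-gene pairs with evidence tags
```

## File dialects

- OCR BED: BED6 + comma-joined timepoint flags + replicate count.
- Loops BEDPE: standard 10 columns + resolution, timepoint, q-value.
- Gene table TSV: `gene_id symbol chrom strand tss_csv biotype`
  (1-based TSS); GTF transcript records are also accepted.
- Summary stats TSV: `variant_id chrom pos p sentinel_id trait [beta se]`
  (1-based positions).
All readers are gzip-transparent.
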