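# immunopanel

Scoring of a fixed 15-gene immune activation/checkpoint panel in bulk
expression data, and early prediction of response to immune checkpoint
blockade (ICB) from on-treatment samples.

Only a minority of patients respond to PD-1 or CTLA-4 blockade, so tools
that flag likely responders early in treatment are valuable. This package
implements, as a tested pipeline, a small biologically motivated panel of
6 immune-activation genes (*IFNG, CXCL9, CXCL10, CD8A, PRF1, GZMB*) and 9
checkpoint-pathway genes (*PDCD1, CD274, PDCD1LG2, CTLA4, CD80, CD86, LAG3,
HAVCR2, BTLA*), together with:

- **ssGSEA scoring** — per-sample, rank-based enrichment
  ES = Σᵢ (P_in(i) − P_out(i)), where P_in is the rank-weighted (r^α,
  α = 0.25) cumulative fraction of the gene set along the sample's
  decreasing-rank ordering and P_out the cumulative fraction of out-of-set
  genes. The *activation*, *checkpoint* and *immunogenicity* scores are the
  enrichment of the 6-, 9- and 15-gene sets.
- **Sum-of-ranks predictor** — rank all cohort samples by each panel gene
  (ascending, ties averaged) and sum a sample's 15 ranks; evaluated by
  ROC/AUC via the tie-aware Mann–Whitney identity. A shipped 15-gene
  non-immune control signature provides the negative control.
- **Statistics** — two-sided Wilcoxon rank-sum (exact by enumeration at
  small n, normal approximation with tie/continuity corrections otherwise)
  and Pearson correlation, with stratified comparison tables.
- **Synthetic cohorts** — a latent immune-infiltration-factor simulator
  that emulates the statistical structure the analysis assumes (tumors
  higher and more tightly coupled than normals; panel genes elevated in
  future responders; control genes independent of everything), so the full
  pipeline is testable without external downloads.

It is aimed at computational-biology users who want a reproducible,
unit-insensitive (everything downstream is rank-based) reimplementation of
this class of immune-signature analysis, on their own matrices or on
simulated cohorts. See `docs/methods.md` for the model details and design
choices.

## Worked example

```python
import immunopanel as ip
from immunopanel import CohortConfig
from immunopanel.panels import load_controls_gmt

# a synthetic 3-tissue tumor/normal cohort: 2,030 genes x 600 samples
cohort = ip.generate_tissue_cohort(CohortConfig(seed=1))
scores = ip.compute_panel_scores(cohort.matrix)
print(scores.head(3).round(2))
r = ip.pearson(scores["immunogenicity"], scores["activation"] + scores["checkpoint"])
print(f"immunogenicity vs activation+checkpoint: r = {r.r:.3f}")
```

```
                    activation  checkpoint  immunogenicity
sample_id
tissue01_tumor_001      878.29      832.05          853.66
tissue01_tumor_002      758.55      593.34          662.72
tissue01_tumor_003      789.78      751.84          769.80
immunogenicity vs activation+checkpoint: r = 0.999
```

The enrichment scores are dimensionless running sums (here on a 2,030-gene
universe); the near-perfect correlation shows the single immunogenicity
score carries the same information as the two sub-scores combined.

```python
# on-treatment ICB cohort: 50 responders + 50 non-responders
icb = ip.generate_icb_cohort(CohortConfig(n_responders=50, n_nonresponders=50, seed=7))
result = ip.predict_cohort(icb.matrix, ip.default_panel(), icb.meta,
                           controls=load_controls_gmt())
print(f"panel pooled AUC   = {result.panel.pooled.auc:.3f}")
print(f"control pooled AUC = {result.control.pooled.auc:.3f}")
```

```
panel pooled AUC   = 0.971
control pooled AUC = 0.540
```

The panel's sum of ranks separates future responders from non-responders
almost perfectly, while the random non-immune control signature is at
chance — response in the generator couples to the panel genes only.

There is also a CLI for the same steps:

```bash
immunopanel simulate --kind icb --seed 7 --out cohort/
immunopanel score   --matrix cohort/matrix.tsv --out scores.tsv
immunopanel predict --matrix cohort/matrix.tsv --meta cohort/metadata.tsv --out pred/
immunopanel run     --config run.yaml --out report/
```

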