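# Methods

## The analysis

`immunopanel` implements a fixed, biologically motivated 15-gene panel for
quantifying tumor immunogenicity and for early identification of future
responders to immune checkpoint blockade (ICB): six immune-activation genes
(*IFNG, CXCL9, CXCL10, CD8A, PRF1, GZMB* — the IFN-γ / T-cell chemotaxis /
cytotoxicity axis) and nine checkpoint-pathway genes (*PDCD1, CD274,
PDCD1LG2, CTLA4, CD80, CD86, LAG3, HAVCR2, BTLA* — the PD-1 and CTLA-4 axes
plus three further checkpoints). Three analysis stages are built around it:

1. **Consistency check.** Activation and checkpoint scores — single-sample
   GSEA (ssGSEA) enrichment of the 6- and 9-gene sets — are compared between
   tumor and normal samples per tissue (two-sided Wilcoxon rank-sum), and
   the activation–checkpoint Pearson correlation is computed per tissue and
   condition. Tissues whose tumor correlation falls below 0.5 are flagged
   for exclusion from a combined 15-gene immunogenicity score.
2. **Validation.** The immunogenicity score is correlated (Pearson, per
   stratum) with independent readouts of immune infiltration — an ordinal
   pathology-like score and a continuous infiltration estimate — with a
   15-gene non-immune control signature run alongside as a negative control.
3. **Prediction.** On an on-treatment ICB cohort, samples are ranked
   across the cohort by each panel gene's expression (rank 1 = lowest, ties
   averaged) and each sample's ranks are summed; the sum of ranks is
   evaluated as a responder/non-responder classifier by ROC/AUC, pooled and
   per treatment arm, against the control signature.

## The ssGSEA statistic

For one sample with N genes, gene g gets rank r_g ∈ [1, N] ascending with
expression (ties averaged). Walking positions i = 1…N down the
decreasing-rank ordering,

    P_in(i)  = Σ_{j≤i, g_j∈S} r_{g_j}^α / Σ_{g∈S} r_g^α
    P_out(i) = |{j ≤ i : g_j ∉ S}| / (N − n),     ES = Σ_i (P_in(i) − P_out(i))

with set size n and exponent α (default 0.25, the ESTIMATE dialect; α = 0
gives the unweighted Kolmogorov–Smirnov-style running sum). Scores are
strictly per-sample — no cross-sample rescaling unless the
`rescale_range` flag selects that dialect.

**Tie dialect.** Positions inside a tied-rank block all carry the
cumulative values at the end of their block (equivalently, a threshold
sweep over distinct expression values). On tie-free data this equals the
classic positional walk exactly; it makes the score independent of how
tied genes are ordered, and constant-expression samples score exactly 0.
The walk order additionally breaks rank ties by gene symbol so exported
running-sum curves are reproducible across platforms. Whether published
ssGSEA implementations share this tie handling is not verifiable from
their descriptions; ties are measure-zero for continuous expression data,
so the choice only matters for coarsely quantized inputs.

**Degenerate inputs.** A set with no gene in the universe, or covering the
whole universe (P_out undefined), is an error; set genes absent from the
universe are dropped with a warning — mirroring how a panel is applied to a
platform that does not measure one gene (e.g. BTLA on some assay panels),
where scoring proceeds on the 14 genes present, without imputation.

## Sum-of-ranks predictor and AUC

Ranking is ascending (low expression = rank 1), so high panel expression
gives a high sum and predicts response; with G genes over S samples scores
lie in [G, G·S]. Missing panel genes are simply omitted from the sum (the
14-gene case); `rescale_by_genes` divides by G·S for cross-cohort
comparability. Ranking is cohort-relative; the default pools both
treatment arms before ranking, and a `per_arm` mode ranks within each arm
(per-arm scores are rescaled to the mean-rank scale before pooling so arms
of unequal size remain comparable). AUC is computed by the tie-aware
Mann–Whitney identity (ties counted half) and asserted internally to equal
the trapezoidal area of the threshold-sweep ROC curve; the two are
mathematically identical, and the assertion guards the implementation.

## Statistics

Wilcoxon rank-sum tests are two-sided. For combined sample size ≤ 12 the
null is enumerated exactly over all C(n1+n2, n1) group assignments of the
pooled values; enumeration handles ties naturally through average ranks, so
it is used for small samples regardless of ties (identical groups give
p = 1 exactly). Larger samples use the normal approximation with tie and
continuity corrections. The exact and asymptotic p agree closely in the
significance-relevant region (within 0.02 for exact p ≤ 0.5 at n = 6+6,
verified exhaustively); near the null centre the exact two-sided p is
discrete with jumps of ~0.13, so no approximation can track it more
tightly there. Pearson correlations use the t-distribution two-sided p.
The significance rule is a flat p < 0.05 by default, matching common
practice for this kind of panel analysis; optional Benjamini–Hochberg
adjustment is available for the stratified tables.

## Synthetic cohorts

The generator replaces external tumor/normal atlases and published ICB
trial tables for all testing. Per sample, a latent immune-infiltration
factor L ~ Normal(μ_condition + δ_tissue, σ_L) drives log2 expression:

    activation gene g:  baseline_g + b_g·L + ε
    checkpoint gene g:  baseline_g + b_g·c_condition·L + ε
    control/background: baseline_g + ε   (5% of background weakly loaded, 0.1·L)

with loadings b_g ~ U(0.8, 1.2), noise ε ~ Normal(0, 0.3), couplings
c_tumor = 1.0 > c_normal = 0.3, and linear-scale expression 2^(log2 value),
so values are positive and per-sample medians positive by construction.
Defaults: 3 tissues, 100 samples per condition per tissue, 2,000 background
genes, μ_tumor = 1.5, μ_normal = 0.5, σ_L = 0.5, tissue offsets
Normal(0, 0.2). Two imperfect readouts of L accompany each cohort:
`true_infiltration` = L + Normal(0, 0.2) (standing in for in-silico
infiltration estimators, which are external published tools and out of
scope here) and `pathology_score` = cohort-quartile binning of L into 0–3
with 15% adjacent-grade label noise (an imperfect pathologist readout).

The ICB cohort is all-tumor, split across anti-PD-1 and anti-CTLA-4 arms;
responders' latent mean is shifted up by `responder_effect` (log2-latent
units, default 1.5 — three within-class latent SDs), raising every panel
gene through its loading while leaving control and background genes
untouched. The default was chosen analytically so the cohort reproduces the
near-perfect discrimination reported for this class of on-treatment
predictor: with shift Δ and within-class SD σ_L, the best attainable AUC is
Φ(Δ/(σ_L√2)) ≈ 0.98 at the defaults, slightly attenuated by per-gene noise
(≈ 0.09/15 extra variance after averaging over 15 genes). Expressing the
shift in absolute latent units (rather than multiplying by σ_L) keeps the
responder separation and the within-class spread independently tunable.
Exact responder counts (`n_responders`/`n_nonresponders`) override the
Bernoulli `responder_fraction` labeling for fixed-size evaluations.

**What the generator does not emulate:** assay probe-level noise, batch
structure, tissue-specific co-expression beyond a per-tissue latent offset,
non-Gaussian expression tails, and any coupling between response and genes
outside the panel. Passing tests therefore demonstrate that the pipeline's
machinery recovers the structure it assumes — not that the panel predicts
response in real patients; that evidence belongs to the underlying studies.

## Numerical and design choices

- All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; no global RNG state. Identical config + seed
  reproduces a cohort and a report bit-for-bit.
- Gene symbols are matched case-sensitively after trimming; a small shipped
  alias table maps protein names (PD-1, PD-L1, TIM-3, …) to symbols at load
  time. Missing values are not permitted in matrices — an unmeasured gene
  is an absent row, not a NaN column.
- The per-sample median (for median normalization) is taken over all genes
  in the universe, zeros included; a zero median is an error naming the
  sample. The log transform x → log2(1 + 1023·x) maps 0 → 0 and 1 → 10
  exactly.
- Breast-like subtype grouping requires user-supplied ESR1/ERBB2 cutoffs on
  log-transformed expression (HER2-high trumps HR-high; both-low is
  TN-like). No default cutoffs ship, because sensible values depend on the
  cohort's expression unit; the antimode of a two-component fit per gene is
  a reasonable procedure.
- Universe intersection keeps the first matrix's gene ordering; argument
  order never changes membership. When merging cohort tables, a sample
  present in more than one table is kept from the earliest table.
- Exact-Wilcoxon cutoff at combined n ≤ 12 (configurable) balances
  fidelity and cost: C(12,6) = 924 assignments enumerate instantly.
- Problem sizes in the test and acceptance runs (600-sample tissue cohorts;
  100 replicate 50+50 and 20 replicate 500+500 ICB cohorts; 2,000
  background genes) were chosen as the smallest scales at which the
  cohort-level quantities are stable to well within the tolerances tested.

## Known limitations

- The sum-of-ranks score is cohort-relative: it cannot score a single
  sample in isolation, which limits direct clinical-assay use.
- The ssGSEA tie dialect and the exact ESTIMATE ordering conventions may
  differ in the last decimals on heavily tied data.
- The pipeline reports per-arm AUCs but makes no attempt to model
  arm-specific biology; arms differ only by label in the generator.
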