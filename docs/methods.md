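# Methods

## Scope and data model

`fractx` operates on integer count matrices (features × samples) with a
sample sheet describing a three-factor design: genotype (`healthy` / `c9`),
treatment (`ctrl_rnai` / `srsf1_rnai`) and fraction (`whole_cell` /
`cytoplasmic`, with `nuclear` accepted in metadata). Feature ids are opaque
strings; transcript- and gene-level matrices are both supported and any
isoform→gene aggregation is the caller's explicit responsibility. Every
contrast requires at least two samples per group, and whole-cell and
cytoplasmic matrices entering the export stage must share a feature id
space and design.

## Normalisation

Size factors follow the relative log expression (median-of-ratios) recipe:
`s_j = median_g counts_gj / geomean_g`, computed over reference features
with strictly positive counts in all samples, then rescaled to geometric
mean one. These factors absorb sequencing depth, so all downstream
normalisation uses the effective library size `s_j · N̄` with `N̄` the
geometric-mean raw library size — a constant that keeps CPM values in
familiar per-million units. This construction makes every between-sample
fold change exactly invariant to rescaling any one sample's counts, which
is the property that matters for DE; using `s_j` *times the per-sample raw
library size* instead would double-count depth and break that invariance.
When no feature is positive everywhere, per-feature geometric means fall
back to positive entries only.

The low-count filter retains features with CPM ≥ 2 (inclusive) in ≥ 2
samples, computed on raw library sizes, since filtering precedes
normalisation. Log-CPM uses a prior count of 0.5 per million scaled per
sample in proportion to effective library size, the common convention.

## Differential expression

Counts are negative binomial with variance `μ + φμ²`. For each feature a
one-way log-link GLM with group means and library-size offsets is fitted by
damped Newton iterations on the per-group score equations (vectorised
across features, so a 2000-feature contrast fits in well under a second).

**Dispersion.** Genewise `φ_g` maximises the Cox–Reid adjusted profile
likelihood (the adjustment subtracts half the log determinant of the
per-group Fisher information, removing most of the small-sample bias of
plain profile likelihood) over a 41-point log-spaced grid on
`[1e-6, 10]` with quadratic refinement. A trend `φ̄(abundance)` is fitted
by lowess (frac 0.4) of `log(φ_g + 1e-4)` on mean log2-CPM. The shrunk
value combines the two on the log scale with weight
`prior_df / (prior_df + resid_df)` toward the trend (prior df 10 by
default), clipped so it always lies between the genewise and trend values.
Estimates at the lower grid bound are reported as exactly zero.

**Testing.** The quasi-likelihood route divides the likelihood-ratio
deviance by a moderated quasi-dispersion: per-feature residual deviance
over residual df, squeezed by assuming `s²_g ~ s₀² F(df, d₀)` and
estimating `(s₀², d₀)` by moment matching on `log s²` (digamma/trigamma
inversion). The statistic `(dev_null − dev_full)/s²_posterior` is referred
to `F(1, resid_df + d₀)` (chi-square with 1 df when `d₀ = ∞`). A plain
likelihood-ratio chi-square mode (`test="lrt"`) is provided; with `φ = 0`
it coincides with a Poisson GLM likelihood-ratio test, which the test-suite
verifies against an independent GLM implementation.

**Selection.** A feature is a DEG when `|log2FC| > log2(fc_threshold)` and
`p < p_threshold` (defaults 2 and 0.05). The p-value is the raw two-sided
p; BH q-values are computed and reported but do not gate the flag — FDR
control at 5% is applied only in the exon-usage stage. Fold changes are
estimated from prior-augmented (0.5 CPM) group mean CPMs, which keeps them
finite for groups with zero counts and exactly scale-invariant. Direction
convention, fixed globally: disease contrast = C9 vs healthy; treatment
contrasts = SRSF1-RNAi vs control-RNAi; positive log2FC means higher in
the first-named (non-reference) group.

For continuous log-scale matrices (microarray-style) `anova_de` runs a
per-feature one-way between-subject ANOVA with the same joint selection
rule; features with zero total variance report `p = 1` and `log2FC = 0` by
convention.

Calibration rather than numeric identity with any existing implementation
is the acceptance surface: on null simulations (2000 features, 3 vs 3,
φ = 0.1) the type-I error at p < 0.05 sits within three binomial standard
errors of 0.05, power for planted |log2FC| = 2 at mean ≥ 100 exceeds 90%,
and mean dispersion recovers a true φ = 0.2 within 25% — the acceptance
suite and `scripts/acceptance.py` recompute all of these.

## Nuclear-export classification

Between two conditions, a transcript with cytoplasmic `|log2FC| >
log2 3` and whole-cell `|log2FC| < log2 3` is inferred to have altered
nuclear export — stimulated when the cytoplasmic change is positive,
inhibited when negative. The whole-cell band is two-sided because
steady-state stability in either direction is what qualifies. The rule is
fold-change-only by design; `require_cyt_p` optionally adds `p < 0.05` on
the cytoplasmic side (off by default). Features absent from either
compartment's post-filter table are *unclassifiable* and reported
separately with a reason — absence of evidence is not evidence of
stability.

## Signature and orthology

The disease-modifying signature is the intersection of the disease and
treatment DEG sets; a member is *reversed* when the two fold changes have
opposite signs. No magnitude criterion is imposed on reversal — a
descriptive restoration metric `|log2FC_disease + log2FC_treated|` is
reported but never used for classification. Venn decompositions are exact
set-region counts. Ordered fold-change matrices use average-linkage
hierarchical clustering on Euclidean distances of the signed pairs, with
deterministic tie-breaking by input order.

Homology is a static two-column table; counting is per homology *pair* so
one-to-many relations expand. Strict concordance requires both sides to be
DEGs and compares fold-change signs; a lenient view admits one-sided pairs
with the sub-threshold side contributing its raw sign, since reported
tallies in this study design can include either convention.
Fully-conserved reciprocal pairs require both genes in their species'
signatures, matching disease directions across species, and reversal
within each species.

## Differential exon usage (simplified)

Each exon of a multi-exon gene is tested against the sum of its gene's
remaining exons between two groups via a 2×2 Pearson chi-square on pooled
counts. Replicate-level variability overdisperses pooled proportions, so
the statistic is deflated by a moderated quasi-binomial dispersion: the
within-group heterogeneity chi-square over its df, squeezed across exons by
the same scaled-F moment matching used in the DE stage and floored at one;
the deflated statistic is referred to `F(1, replicate df + prior df)`.
BH adjustment runs across all tested exons with significance at q < 0.05.
Single-exon genes are excluded (logged), genes with an all-zero group are
skipped, and a gene-level rollup ("gene has ≥ 1 significant exon") is
provided explicitly as an interpretation. This stage is a deliberately
simplified exon-centric test; its acceptance surface is FDR calibration
(mean false-discovery proportion ≤ 0.10 across 20 null replicate runs of
~1000 exons) and power (a 0.5 → 0.1 usage shift at gene counts ≥ 10⁴ is
detected), not replication of any per-exon GLM framework's statistics.

## Diagnostics

Fold coverage is `(m · L · N) / (G · t)` with `m = 2` for paired-end
reads, `L` read length, `N` reads (pairs when paired), `G` genome size and
`t` the transcribed fraction; the canonical design of 2 × 150 bp × 104×10⁶
read pairs over 10% of a 3 Gb genome gives 104-fold. Sample MDS is
classical (Torgerson) scaling of Euclidean distances on the top-500 most
variable log-CPM features — classical rather than stress-minimising so
that at full rank the embedding reproduces distances exactly; axis signs
are canonicalised (largest-magnitude loading positive) for determinism.
Marker summaries report the mean CPM of a marker set on the log2 scale
with a floor of 2⁻¹⁰ CPM (so all-zero sets sit at a defined floor and the
summary is exactly linear in counts above it), together with the fraction
of marker ids found.

## Synthetic data generator

The generator emulates the paired-fraction study design: 3 individuals per
genotype by default, each contributing whole-cell and cytoplasmic samples
under both treatments (24 samples). Per feature: baseline log2 expression
~ Normal(5, 2) (several orders of magnitude of abundance), NB dispersion
log-normal around 0.1, cytoplasmic fraction `f_g` ~ Uniform(0.2, 0.9).
Per individual and feature, a Normal(0, 0.3 log2) jitter models
inter-individual baseline variability and is shared across that
individual's samples, preserving individual identity across treatments and
fractions. Expected whole-cell counts scale relative abundances to a
per-sample library size (0.8–1.2 million by default); cytoplasmic means
are `f_g` times the same latent mean, times `2^{export effect}` under
SRSF1-RNAi — export effects touch the cytoplasm only. Counts are NB draws;
all randomness flows from one seed through named child streams, so a
config reproduces bit-identical data.

Planted effects: 100 disease features (|log2FC| 1.5–3), of which 30 are
reversed and 5 concordantly shifted by treatment; 20 treatment-only
features; 50 export features (|log2FC| 2–3). `min_effect_log2mean`
restricts effect planting to features above an abundance floor for
scenarios that specify a minimum mean count. Exon counts split gene counts
multinomially across 2–6 exons with fixed per-gene Dirichlet proportions;
altered genes shift their first exon's usage 0.5 → 0.1 between genotypes,
conserving gene totals exactly. The two-species constructor links planted
features across two independently simulated datasets: reciprocal pairs are
reversed in both species with matching disease signs, conserved pairs
share disease signs without treatment effects, opposite pairs differ in
sign, plus null–null links.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: GC/length bias, isoform-level quantification
uncertainty, correlated features (co-regulation), compositional
distortions from very large effect fractions, batch effects, disjointness
of treatment responses between genotypes, or nuclear-fraction counts. The
recovery benchmarks show the pipeline's statistics are calibrated and its
set logic exact under the stated generative assumptions; they cannot
certify performance under violations of those assumptions.

## Numerical choices and limitations

- Dispersion grid `[1e-6, 10]`, 41 log-spaced points plus quadratic
  refinement; estimates at the bottom of the grid report as 0.
- Newton GLM fits: 60 damped iterations, step clipped to ±3 on the log
  scale, convergence at 1e-10.
- Trigamma inversion by Newton iterations (60 max, relative tolerance
  1e-10); moment matching falls back to infinite prior df when the
  log-variance residual is non-positive.
- Fold-change prior 0.5 CPM; log-CPM prior count 0.5 per million.
- Degenerate ANOVA features (zero variance) report p = 1; zero
  within-group but nonzero between-group variance reports p = 0.
- Clustering ties resolved by input order (the standard agglomeration
  convention); duplicated rows are guaranteed adjacent.
- The QL machinery is intentionally simpler than reference DE packages (no
  robust outlier weighting; a single lowess trend): simulation calibration,
  not numeric identity, is the contract.
- Problem sizes in the evaluation scenarios (2000 features, triplicates,
  20 exon-usage replicates) are desk-scale choices that keep every
  scenario under a few seconds while leaving binomial error bars tight
  enough for the stated criteria.
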