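# Methods

This note records the models implemented in `dualscreen`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying procedures are
conventionally under-specified.

## Count model and quality control

Pooled-screen counts are modeled as negative binomial with the
size/dispersion parameterization, var = μ + μ²/dispersion, so the Poisson
limit is recovered as dispersion → ∞.  Guide (or construct) abundances carry
a log-normal skew; a small fraction of constructs can be down-weighted to a
poorly represented tail, which is what produces the zero-count ("missed
guide") entries seen in real sequencing summaries.

QC statistics follow screen-sequencing conventions:

- **Mapping ratio, missed-guide and threshold percentages** are exact integer
  ratios rounded *half-up* to two decimals (`decimal`-based, not banker's
  rounding), matching how sequencing summaries print them.  Rows absent from
  a count table count as zeros against the nominal library size.
- **Gini index** is computed on raw per-sample counts including zeros, with
  the population (n²) denominator: G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄), evaluated via the
  sorted-vector identity.  Raw counts are used because the statistic is meant
  to flag dropout and unevenness before any normalization; it is
  scale-invariant, so sequencing depth cancels.  The default read threshold
  for the "above threshold" column is 10 (configurable); count tables do not
  record what threshold an upstream pipeline used, so it must be stated with
  the report.
- **Correlations and PCA** act on log2(count + 1) profiles.  The pseudocount
  of 1 is the zero-safe convention; constant samples yield an undefined (NaN)
  correlation rather than a silent zero.

## Gene essentiality (β scores) and re-sensitizers

Counts are normalized by control-guide median-ratio size factors: for each
sample, the median over control guides of count/geometric-mean, computed on
guides with positive counts everywhere.  Guide log2 fold changes compare
each Tend replicate against the pooled mean of the T0 replicates — the
screen branches into arms after T0, so a single shared baseline is the
faithful reference.

β(gene, arm) is the mean over the gene's guides of the replicate-averaged
LFC.  This deliberately transparent estimator shares the sign convention and
approximate log2 scale of likelihood-based scorers (negative = depleted =
essential), so the conventional ±1 cutoffs carry over, while being
deterministic and auditable.  Significance comes from a permutation null:
the mean LFC of same-size guide sets drawn from all targeting guides
(shared per guide-count class, 10,000 draws by default), two-sided p =
(1 + #extreme)/(n+1), Benjamini–Hochberg FDR within each arm.

Re-sensitizer selection takes genes with β > +1 untreated and β < −1 under
drug, i.e. knockouts the cells tolerate (or mildly benefit from) until drug
exposure makes them lethal.  Both thresholds are configurable: a defensible
alternative reading of "tolerated" is |β| ≤ 1, and the CLI exposes
`--thr-control`/`--thr-drug` so either convention can be applied without
code changes.

The drug-combination additivity test adds the two single-agent inhibition
fractions replicate-wise and compares the sum with the combination group by
a two-sided Welch t-test; the verdict is synergistic/antagonistic by the
sign of the difference at p < 0.05, otherwise additive.

## Dual-knockout interaction scoring

Single-knockout fitness is estimated from safe pairings: f(guide) = mean LFC
of the guide's safe-paired constructs over both cassette positions;
f(gene) = median over the gene's guides.  Interaction deltas
δ = LFC − (f_left + f_right) are computed at gene or guide resolution, and
four scores aggregate them per unordered gene pair (up to 3×3 guide
combinations × 2 orientations = 18 constructs):

- **horlbeck** — mean of gene-level deltas;
- **median** — median of gene-level deltas; the background-normalized (B)
  variant first subtracts the median delta of safe–safe constructs;
- **sgrna** — guide-resolution deltas averaged per orientation and then
  across orientations; the B variant subtracts the safe–safe mean.  Guide
  resolution removes the bias the gene-median correction retains when one
  guide of a gene has deviant efficiency;
- **rra** — robust rank aggregation: guide-level deltas are converted to
  ascending percentile ranks over all constructs, and each pair's
  ρ = min over k of the Beta(k, n−k+1) CDF at its k-th smallest rank.
  Guide-level deltas are used because rank aggregation conventionally
  operates at sgRNA resolution.  An optional permutation p-value shuffles
  the construct-to-pair assignment.

Same-gene constructs (both positions targeting one gene) are excluded from
pair scoring; pairs involving the safe pseudo-gene are never scored.  Pairs
observed with fewer than 4 constructs are flagged low-confidence rather
than dropped.

**Consensus**: per method the ⌈0.10 · n_pairs⌉ strongest-SL pairs (most
negative score; smallest ρ) are flagged, and pairs flagged by ≥ 3 methods
form the consensus set, with Venn-region counts per method subset.  The B
and NB variants of the median and sgRNA scores differ by a constant and
rank identically, so they count as one method each; the method list and
`min_methods` are parameters for users who want to emulate larger method
panels.

A known property of this consensus, visible in the acceptance computation:
because all methods are re-aggregations of the same construct deltas, their
null scores are substantially correlated (the mean–median correlation alone
has a ≈ 0.8 floor for symmetric noise), so the top-decile sets of different
methods overlap well beyond independence.  Against planted truth this makes
consensus recall excellent but caps its precision when true interactions
are sparse; decorrelation grows with guide-efficiency heterogeneity, which
separates the gene-level from the guide-level methods.  Users who need a
high-precision call set should treat `min_methods = 4` or an explicit score
threshold as the stringent option.

Candidate-gene selection for a dual library intersects three criteria:
membership in the cell-death hallmark list, expression above 50 read counts,
and non-essentiality |β_control| ≤ 1 (the null band of the genome screen).
The SL network is the simple undirected graph of consensus pairs; hub genes
have degree ≥ 10.

## Cell-line representativeness

Inputs are log2 expression matrices with sample metadata.  Preprocessing
removes probes below background in ≥ 80% of samples (boundary inclusive)
and collapses multi-probe genes by median.  Batch effects are removed by
per-gene batch mean-centering (the fixed-effect special case of regression
batch correction); for batch-balanced group designs this provably leaves
group contrasts unchanged.

- **Differential expression**: per-gene Welch t-test on log2 values with BH
  adjustment; fold change reported on the signed linear scale
  (FC = 2^Δ for Δ ≥ 0, −2^(−Δ) otherwise) so "FC > 1.5 or < −1.5" applies
  literally; selection additionally requires adjusted p < 0.01.
- **Co-clustering**: average-linkage hierarchical clustering on 1 − Pearson
  distance over samples, cut at k = 2.  Linkage, distance and k are
  configurable because the procedure is conventionally reported without
  them.  A cell line is labeled 1 when its cluster contains the strict
  majority of non-responder samples — the operationalization of "clusters
  with the non-responders".
- **Spearman ranking**: the top-2000 most variable genes across the
  cell-line panel (sample SD, ties broken by gene name), then the mean
  Spearman correlation of each cell line with every non-responder sample;
  label 1 for rank ≤ 100.  Constant vectors are excluded from the average
  rather than contributing a fabricated zero.
- **ssGSEA**: per sample, genes are ranked by expression (ties broken by
  gene name for determinism) and each set's enrichment score is the sum
  over ranked positions of the rank-weighted in-set ECDF (weight = rank^α,
  α = 0.25) minus the unweighted out-of-set ECDF, normalized by the global
  max − min of the score matrix — the standard single-sample enrichment
  convention.  The implementation is verified against an exhaustive
  brute-force walk on all small cases.

The overall score is the sum of the three binary labels (0–3); ranking is
by score, ties broken by the average Spearman correlation.

## Synthetic-data generators

All generators are bit-reproducible for a fixed seed and return their truth
object alongside the data.

**Genome screen** (default desk scale: 2,000 genes × 3 guides + 100 safe
guides, triplicate T0/control/drug, ~500 reads per guide): T0 counts are NB
around depth × abundance; Tend means are scaled by 2^(f + β + jitter) with
per-guide jitter ~ N(0, τ = 0.3) representing guide-efficiency variation.
Planted re-sensitizers use (β_control, β_drug) = (1.5, −2).

**CDKO screen** (default desk scale: 40 genes × 3 guides + 10 safe guides →
16,900 constructs and 780 screened pairs, triplicate, ~300 reads per
construct): the true construct LFC is f_i + f_j + γ(pair) + ε with
construct-level ε ~ N(0, 0.35) shared across replicates; 20 pairs are
planted at γ = −2.  The safe-guide fraction (~8% of the library) mirrors
typical dual-knockout library design; depth, dispersion (400) and the
abundance skew (σ_log = 0.04 with a 0.5% low-abundance tail) are set so
that a null screen shows the sequencing signature of a well-executed
experiment: T0 Gini ≈ 0.05 and a sub-percent zero-count rate.  A
`noiseless=True` mode emits exact expected counts (real-valued), which
turns the closed-form identities of the scoring chain into machine-precision
tests; the full 230-guide design is available behind `full_scale=True`.

**Transcriptome cohort** (default: 29 non-responders vs 15 responders across
three batches, 1,500 genes, five cell lines): patient expression is
baseline + δ·(non-responder) + batch offset + N(0, σ = 0.5), with 150
planted DEGs shifted by ±1.5 log2 units (half up, half down — a uniform
shift would be invisible to correlation-based clustering).  Cell line c is
the mixture λ_c · (non-responder centroid) + (1 − λ_c) · (independent
centroid) + noise, with λ ∈ {0.9, 0.7, 0.5, 0.2, 0.0} by default.  The
synthetic hallmark-shaped gene-set collection concentrates planted DEGs in
a quarter of its sets so pathway-level profiles discriminate the response
groups.

What the generators do **not** emulate: PCR chimeras and cassette
recombination, copy-number-driven depletion artifacts, guide off-target
effects, heavy-tailed outlier constructs, microarray probe-level noise, or
cohort heterogeneity beyond a scalar batch offset.  Passing recovery tests
therefore demonstrates correctness of the analysis chain under the stated
generative model, not robustness to every real-data pathology.

## Numerical conventions

- Percentages: decimal half-up rounding to 2 decimals.
- LFC pseudocount: 1 by default (0 in exactness tests on noiseless data).
- Deterministic tie-breaks throughout (gene/pair name as secondary key), so
  reruns and column permutations give identical outputs.
- Permutation p-values use the (1 + k)/(1 + n) estimator; they are never 0.
- Degenerate inputs are explicit: all-zero vectors, constant samples and
  missing labels raise or mark NaN rather than silently coercing.

## Known limitations

- The β estimator is a mean of guide LFCs, not an NB regression; it matches
  the conventional score's scale approximately, and very low counts affect
  it through the pseudocount.
- Inter-method correlation bounds consensus precision when true
  interactions are sparse (discussed above).
- Per-batch mean-centering removes only additive batch effects; it does not
  protect unbalanced designs from confounding.
- The permutation null for β shares draws within guide-count classes, which
  makes p-values marginally uniform but weakly dependent across genes.
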