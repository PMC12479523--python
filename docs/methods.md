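# Methods

## The screen

The pipeline quantifies directional similarity between microbiome-associated
host gene signatures and drug perturbation signatures.

**Association stage.** For a feature matrix X (samples × taxa, relative
abundances; or samples × metabolites, intensities) and a host expression
matrix E (samples × genes), each (feature, gene) pair gets a Spearman
correlation: midrank both vectors (average ranks for ties), Pearson-correlate
the ranks, and take the two-sided p-value from t = ρ√(df/(1−ρ²)) with
df = n−2. This asymptotic t approximation is the default of the standard
correlation routines for tied data; an exact permutation p is available for
n ≤ 9 (`CorrelationConfig.exact_small_n`). Missing cells are excluded
pairwise (`n_used` records how many complete pairs remained; records below
`min_pairs`, default 5, are dropped). Constant vectors have no defined
correlation and are skipped with a logged count, never imputed.

For metabolite–gene associations the *partial* Spearman correlation controls
for Lactobacillus dominance: x, y, and each covariate column are midranked,
the least-squares projection onto [1, Z_ranked] is removed from ranked x and
ranked y, and the residuals are Pearson-correlated with df = n−2−k. With no
covariates this reduces bitwise to the plain statistic. Rows with a missing
value in x, y, or Z are dropped listwise. The dominance covariate may be
binary (dominant vs not) or a continuous proportion; both work because the
covariate is itself rank-transformed.

**Multiple testing.** Benjamini–Hochberg step-up, implemented directly
(sorted q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, clipped at 1, stable order for ties).
The default family is *per feature across its genes* — one family per
microbe or metabolite — matching the per-feature gene-list framing of the
screen; a single global family is a config switch (`adjust_scope`). A
feature's signature is then up = {gene : Q ≤ α, ρ > 0} and
down = {gene : Q ≤ α, ρ < 0} at α = 0.05; ρ = 0 has no direction and enters
neither set.

**Similarity stage.** Every feature signature is compared with every drug
signature by Fisher's exact test, up-set vs up-set and down-set vs down-set
(concordant directions only by default; reversal comparisons are
implemented behind `include_cross_direction`). The p-value is computed from
the hypergeometric distribution; two-sided uses the minimum-likelihood rule
(sum of point probabilities ≤ observed × (1+10⁻⁷), the convention of R's
`fisher.test`), and margins are put in canonical order so the test is
exactly symmetric in its two sets. The **gene universe** is the single most
result-sensitive choice the screen makes and is surfaced in every result's
metadata: the default is the intersection of the correlation-stage gene
universe and the drug-catalog universe, because overlap can only be observed
among genes measured on both platforms; union and explicit-list policies are
available. Q-values are BH-adjusted within one family per direction across
the whole feature × drug grid (per-feature and per-drug families are config
options — the true family of the original analyses is not recoverable, so
the default is documented rather than asserted). Results carry
−log10(Q) capped at 16, with Q = 0 mapped to the cap, so similarity
matrices stay finite for serialization and plotting.

**Clustering and reports.** Drugs (and optionally features) are clustered by
agglomerative complete linkage on Euclidean distances between their
−log10(Q) profiles — the matrix as plotted, not raw p-values or odds
ratios, so the dendrogram reflects exactly what the heatmap shows. The
linkage is implemented in-package with a deterministic tie-break (tied
minimum distances merge the pair with the lexicographically smallest leaf
indices); merge heights are identical to standard complete linkage (verified
against scipy and a from-scratch oracle). Missing screen cells enter the
matrix as 0 — "no evidence of similarity" is the matrix's semantic zero.
Ranked mimic tables sort by ascending Q, then descending odds ratio, then
identifiers; all plotted numbers are serialized to TSV before any figure is
rendered.

**Culture metabolomics.** A metabolite is *produced* by a strain when the
mean supernatant intensity exceeds the uninoculated-medium control mean by
log2 fold-change ≥ 1, *consumed* at ≤ −1, else *unchanged*. A pseudocount
(half the smallest nonzero intensity in the profile) is added only when an
arm mean is zero, so clean fold changes are exact and zero-mean arms stay
finite. This rule is deliberately minimal — a transparent deterministic
classifier with no inferential test at triplicate-scale n; it is this
package's own definition, since no standard formula exists for
Metabolon-style produced/consumed calls.

## The synthetic cohort generator

The generator emulates the *structure* of a paired vaginal multi-omics
study, not any particular dataset: 90 samples, 2000 host genes (reduced
from microarray scale for test speed; larger values are just config),
51 taxa, 99 metabolites, and a 35-drug catalog in 5 mechanism classes.

Construction, in order:

- **Dominance covariate** D ~ Bernoulli(0.5) per sample; the taxon named
  `LACTOBACILLUS` has its logistic-normal latent shifted by 2.5·D before
  the per-sample softmax that yields relative abundances. Compositional
  closure means other taxa anti-correlate with dominance, as in real
  communities.
- **Metabolites** are log-normal intensities; confounded metabolites
  (30% of planted metabolite effects, per `confounded_fraction`) have
  their latent shifted by 1.5·D.
- **Planted effects**: each planted feature contributes
  effect·link(normal-scores(feature)) to its target genes against Gaussian
  noise (σ = 1), where `link` is drawn per gene from {identity, standardized
  cube}. Links are strictly increasing but not linear: Spearman's premise
  is monotonicity, and the generator must not secretly favor settings where
  Pearson would do. Defaults: 6 planted taxa and 10 planted metabolites,
  30 up + 30 down genes each, effect size 1.5. At these settings the
  per-gene signal (ρ ≈ 0.8 at n = 90) is strong — the generator tests
  recovery of a real effect, not borderline power.
- **Confounded pairs** receive ±1.5·D on the gene side and nothing else:
  plain Spearman flags them (false-positive rate ≈ 0.98 at n = 100),
  the dominance-adjusted partial correlation correctly does not
  (rate ≈ 0.05).
- **Drug catalog**: each mechanism class shares a core per direction —
  65% of one anchor feature's planted genes plus 45 random non-planted
  filler genes — and every drug adds 40 private random genes (≈115-gene
  sets, the scale of L1000 signatures). Anchoring classes to distinct
  planted features is what makes classes separable in the screen's
  similarity matrix, mirroring the internal validation that mechanistically
  similar compounds cluster together. **Mimicry pairs** additionally give
  the drug 50% of a target feature's planted up/down genes; mimicry
  features carry larger signatures (80 + 80 genes) so the planted mimics
  dominate the anchor-driven class signal and occupy the top ranks
  unambiguously. Metadata is stamped MCF7 / 10 µM / 24 h so default catalog
  filters pass.
- **Reproducibility**: one mandatory seed feeds a root `SeedSequence`;
  every matrix draws from its own spawned substream, so outputs are
  bit-identical for a given config.

What the generator does **not** emulate: real taxon covariance structure
and compositional constraints beyond non-negativity, L1000 measurement
noise and its moderated z-scoring, probe-to-gene collapsing, batch effects,
or realistic effect-size distributions. Passing the recovery tests
therefore shows the pipeline's statistics are correct and well-calibrated
under monotone effects with a known confounder — it does not certify power
or error rates on any real cohort.

## Numerical choices and degenerate inputs

- Midranks everywhere; gene identifiers uppercased and trimmed before any
  set operation (microarray and L1000 symbol conventions differ in case).
- |ρ| = 1 maps to p = 0 (the t statistic diverges); q = 0 maps to the
  −log10 cap (16) rather than infinity.
- Odds ratio conventions: 0/0 → NaN (undefined), x/0 → +inf.
- A two-sided Fisher sum over the entire support is set to exactly 1
  rather than a float-error sum.
- Rank-deficient covariate matrices raise a collinearity error; a variable
  that is constant after filtering raises an undefined-correlation error
  (bulk routines skip and count such pairs).
- Ranked-profile cutting breaks score ties lexicographically by gene id, so
  signatures are identical across runs and input orderings.
- `align_samples` orders the intersection by the first input's sample
  order, making alignment idempotent and order-independent.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: 200 random instances
(|U| ≤ 40) for the exact-test oracle, 100 random vectors (lengths 1–10⁴)
for BH, 100 tied random cases per correlation oracle, 2000 replicates at
n = 100 for the confounding false-positive rates, 20 cohorts at the default
conditions for mimicry recovery / null calibration / class-recovery
(ARI ≥ 0.9), and 50 random 5-item instances for the linkage oracle. These
sizes give stable Monte-Carlo estimates at desk scale; all are constants at
the top of the relevant tests and script and can be raised freely.

## Known limitations

- The asymptotic t p-value for (partial) Spearman is approximate for small
  n and heavy ties; exact enumeration is provided only for n ≤ 9.
- BH controls FDR under independence/PRDS; correlated genes in real data
  weaken the guarantee. The null-calibration test uses an
  independence-like construction.
- The screen's verdicts depend materially on the universe policy; users
  comparing against published overlap counts must match universes first.
- The culture classifier is thresholded fold-change only — with n = 3
  replicates a formal test would be underpowered, but the rule will
  mislabel metabolites with high replicate variance near the threshold.
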