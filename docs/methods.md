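# Methods

This document records the statistical model behind each analysis stage,
the synthetic-data generator and its defaults, the numerical choices, and
the known limitations. Everything stated here about behavior is computed
by the test suite or by scripts in this repository; no empirical claim is
made that the code does not verify.

## 1. Isoform switches

**Quantity.** Isoform fraction IF = TPM_isoform / TPM_gene per sample,
with gene TPM the sum over the gene's isoforms. dIF is the difference of
condition means (silenced − control).

**Filters.** Genes with mean TPM < 1 in *both* conditions are excluded
(unquantifiable usage); isoforms with IF < 0.01 in both conditions are
excluded (never-used isoforms only add BH burden). A replicate in which
the gene's TPM is zero yields an undefined IF for that replicate and is
ignored by the test.

**Test.** Welch's two-sample t-test on the replicate IF values per
isoform, BH-adjusted across all tested isoforms. An isoform switches when
adjusted p ≤ 0.05 *and* |dIF| ≥ 0.1. The 0.1 usage cutoff is the
conventional isoform-switch threshold; with only 3 + 3 replicates a pure
p-value rule would be dominated by variance estimation noise. Constant
replicate IFs yield p = 1 (no evidence of change, not a division error).

**Consequences.** For every significant up/down isoform pair within a
gene, per-feature gain/loss is computed from the isoform annotations (ORF,
UTR5/3 length, domain count, intron retention, NMD insensitivity, coding
status). Length features count as changed only beyond 5% relative
difference so a few nucleotides of annotation jitter do not register.
Per-feature gain fractions get an exact binomial test against 0.5, BH
across features. Switch pairs with exon structures are additionally
classified into ASE classes (ES/MES/IR/A5/A3/ATSS/ATTS) by comparing
sorted exon chains; classification is strand-aware, so A5 and A3 (and
ATSS/ATTS) swap under strand flip.

## 2. Differential splicing (ASE level)

**Quantity.** Length-normalized PSI per sample:
PSI = (I/ℓ_inc) / (I/ℓ_inc + S/ℓ_skip), with inclusion reads supported by
two junctions (effective length ratio 2:1 against skipping). A sample with
I = S = 0 has undefined PSI.

**Filter.** An event is kept only if, in *each* condition, at least two
samples have ≥ 10 total supporting reads (inclusion + skipping). This is
the minimal support under which a two-sample comparison of proportions is
meaningful at 3 + 3 replicates; the ≥ 10 boundary is inclusive.

**Test.** Welch's t-test on arcsine-√PSI per event. The arcsine square
root is the classical variance-stabilizing transform for proportions; on
raw PSI the variance vanishes near 0 and 1 and the t-test is
anti-conservative for extreme events. BH across events; significant means
adjusted p ≤ 0.05 and |dPSI| ≥ 0.05 (dPSI on the raw scale, silenced −
control). Events with fewer than two defined PSI replicates in either
condition are skipped with a warning. Identical conditions give p = 1.

## 3. RBP motif enrichment

**Scanning.** PWM log₂-odds scores against a uniform background, floored
into 0.01-bit bins. The full null score distribution is computed exactly
by dynamic-programming convolution over positions (the binning makes the
support finite); the score threshold is the smallest *attainable* binned
score whose background tail probability is ≤ 0.001. A PWM for which no
attainable score reaches the cutoff (e.g. a uniform PWM, or any 4-mer
against a 0.001 cutoff) is "unscannable": it gets an infinite threshold,
zero hits, and a warning — not an error, since real PWM collections
contain low-information entries. Scanning is sense-strand only, windows
containing unknown letters never match, and overlapping hits all count.
Acceptance test 1 verifies the DP distribution exactly against brute-force
enumeration over all 4^L words.

**Regions.** For each regulated event: upstream flank, spliced region and
downstream flank, with ±200 nt flanks (±100 for MX to avoid overlap
between the two alternative exons' regions). Coordinates are transcript
oriented: on the minus strand the flanks swap and sequences are
reverse-complemented. Flanks truncated at chromosome bounds produce a
warning. An event is "up" if dPSI > 0.05-significant with positive sign,
"down" with negative sign; events with |dPSI| < 0.01 and p > 0.05 form the
null pool, and everything in between is left out of both sets so that the
contrast is between clearly-changed and clearly-unchanged events.

**Statistic.** For each (motif, ASE type, region label, direction) cell:
the observed hit count over the target regions is compared with 100
control sets sampled from the null pool of the same ASE type and region
label, each set matching the target set's cardinality and, per region,
nearest in sequence length (tie-inclusive). z = (obs − mean)/sd with the
sd over the 100 sets (ddof = 1); enriched ⇔ z > 1.96. If the control sd
is zero the z is undefined and the cell is flagged degenerate; it is
called enriched only if the observed count exceeds every control count.
When the null pool is smaller than the target set, sampling falls back to
with-replacement with a warning.

**Counting modes and calibration.** "Observed frequency" defaults to the
total hit count over the target set; a per-sequence binary count (each
region contributes at most 1) is available via `per_sequence=True`.
Measured properties of the statistic on fully null simulations (see
`tests/test_acceptance.py`):

- The null exceedance P(z > 1.96) is not the nominal 2.5% but ≈ 4–5%,
  for three stacking reasons: control sets are drawn *without*
  replacement from a finite pool (their variance underestimates the
  target's by roughly 1 − m/N), hit counts are right-skewed, and the
  control mean and sd are themselves estimates from 100 sets.
- Total-occurrence counting is further inflated for low-complexity
  (repeat-like) PWMs, whose overlapping hits clump and fatten the null
  tail; per-sequence counting removes that overdispersion. For such
  motif collections, per-sequence mode is the calibrated choice.
- The z rule degrades in the rare-hit regime. Under the 0.001 scan
  cutoff a 7-mer PWM effectively matches only its exact consensus
  (adding the one-mismatch class already exceeds the cutoff), so null
  counts per set are ~Poisson(1) and one or two chance hits cross
  z = 1.96; the per-cell false-enrichment rate then reaches ~10%.
  Interpret enrichment calls for long/sharp motifs with small expected
  hit counts accordingly — the degenerate-null flag marks the worst of
  these cells.
- Planting one motif's consensus into sequences creates junction
  occurrences of any *other* motif whose consensus shares a
  suffix/prefix overlap of k letters (probability 4^-(L−k) per plant).
  Enrichment of a motif therefore genuinely propagates to similar
  motifs; this is a property of sequence overlap, not a calibration
  error, and it is why the recovery acceptance test uses
  dissimilarity-filtered motif sets.

## 4. Cohort association

**Correlation.** Spearman's ρ between event PSI and marker expression,
computed as Pearson on midranks; for n ≤ 10 the p-value is an exact
permutation enumeration (chunked), otherwise the large-sample
approximation. Samples with missing PSI are dropped per event; constant
vectors are skipped with a warning.

**Group comparisons.** Three per event: ER+ tumor vs normal, ER− tumor vs
ER+ tumor, and marker-high vs marker-low within ER+ tumors (split at the
ER+ cohort median; ties go to the low group). Each uses the rank-sum test
(exact for n ≤ 12 without ties, normal approximation with tie correction
otherwise; all-identical data give p = 1). Events flagged in all three
comparisons form the headline list.

**Survival.** Median-PSI split (ties low) per endpoint (OS, DFS);
Kaplan–Meier estimates per group and a log-rank test. The log-rank χ²
statistic is computed directly from the risk tables; for n ≤ 10 without
censoring the p-value is an exact permutation over group labelings,
otherwise the χ² approximation (verified against lifelines). A constant
PSI that empties one group is an error naming the event.

**Overlap utilities.** Exact hypergeometric upper-tail test for gene-list
overlap; interval-tree peak overlap with events (gene body, and exon
region extended ±200 bp, half-open, strand-agnostic, hard error on
assembly mismatch). `de_plumbing` is a deliberately simple stand-in for a
DE pipeline: library-size normalization, an expression floor (> 10
normalized counts in ≥ 3 samples), log2 fold change of condition means
with pseudocount 1, Welch on log counts, BH, flag at |log2FC| > 0.2 and
adjusted p < 0.05. It exists to feed the overlap analyses, not to compete
with negative-binomial DE models.

## 5. Synthetic-data generator

All generators derive from one `SimulationConfig.seed` through independent
per-stage `SeedSequence([seed, stage])` streams, so adding a stage never
perturbs another stage's draws and every output is reproducible to the
byte.

**Isoform experiment** (defaults: 500 genes, 2–4 isoforms each, 3 + 3
replicates). Gene expression is log-uniform; baseline isoform usage is
Dirichlet. In 10% of genes a planted switch moves usage dIF = 0.3 from
one isoform to another in the silenced condition. Replicate TPMs get
log-normal noise (sdlog 0.06, mean-corrected so the expected TPM equals
the truth; verified unbiased within 3% over 2000 replicates). The sdlog
matches the few-percent replicate CV of deeply sequenced cell-line RNA-seq
on abundant genes; real data have an additional low-expression noise floor
the generator does not model.

**Splicing events** (defaults: 130 ES / 35 IR / 18 A3 / 11 A5 / 9 MX
≈ 64/17/9/5/4%, the ES-dominated composition typical of perturbation
studies). Junction counts are beta-binomial around the true
length-weighted inclusion probability (depth 300, intra-class ρ = 0.002 —
mild overdispersion as seen between RNA-seq replicates; 5% of events are
simulated at one tenth the depth to exercise the support filter). In 20%
of events a planted |dPSI| = 0.2 is applied, 70% positive — the sign
imbalance mirrors the observation that silencing shifted most events
toward inclusion.

**Region sequences.** Background is i.i.d. uniform ACGU. In regions of
regulated events the designated planted motifs' consensus is written at
Poisson(3 per kb) uniform offsets. Uniform background is a deliberate
simplification: real flanking sequence has composition bias, repeats and
conservation structure, so real-data enrichment z-scores will be noisier
than on this generator.

**Cohort** (defaults: 143 ER+ tumor / 36 ER− tumor / 21 normal = the
773:192:113 proportions of the TCGA breast cohort scaled to 200 samples).
PSI–marker correlation is planted through a Gaussian copula with beta
marginals (concentration 20); the latent correlation uses the exact
inversion r = 2·sin(π·ρ_s/6), so the *Spearman* correlation matches the
target (verified: measured 0.40 ± 0.01 at n = 4000 for target 0.4).
Survival is exponential with the planted hazard ratio applied to
above-median-PSI samples; uniform censoring between 200 and 3000 days
gives ~40% censoring at the default hazard, in the range of clinical
cohorts. 5% of PSI values are set missing.

## 6. Numerical choices

- BH adjustment is computed with the standard step-up algorithm
  (monotonicized from the largest p); NaN p-values propagate to NaN
  adjusted values without affecting other entries. Cross-checked against
  statsmodels `multipletests` on random vectors.
- PWM scores are floored to 0.01-bit bins before convolution; the same
  binning is used for scanning and for the null, so threshold comparisons
  are exact, not approximate.
- All TSV output uses `%.10g` float formatting and `\n` line terminators,
  which is what makes CLI reruns byte-identical across platforms.
- Exact small-sample paths (Spearman n ≤ 10, rank-sum n ≤ 12, log-rank
  n ≤ 10 uncensored, hypergeometric) are verified against brute-force
  enumeration in the acceptance suite.

## 7. Design decisions

- statsmodels-style Model/Results split: `Model(data, options).fit()`
  returns an immutable Results object holding tidy DataFrames plus
  `summary()`; all computation lives in plain functions the Results
  objects call, so every step is unit-testable without a model.
- The enrichment null is resampling-based rather than analytic because
  the hit-count distribution depends on sequence length, composition and
  motif self-overlap in ways no closed form captures; the price is the
  ~4–5% (not 2.5%) null exceedance quantified above.
- The direction classification deliberately leaves a gray zone
  (significant-but-small or large-but-insignificant events belong to
  neither the regulated nor the null set) so that control sets are drawn
  from clearly unchanged events only.
- Welch tests are used throughout for condition comparisons: with 3 + 3
  replicates, pooling variances buys little and risks anti-conservatism
  under variance heterogeneity.

## 8. Limitations

- 3 + 3 replicates give limited power: at the default depth and planted
  |dPSI| = 0.2, only a fraction of planted ASEs reach significance after
  BH. Effect-size estimates of the significant calls are accurate; the
  call list is conservative. The switch analysis, with its larger
  per-gene effect (dIF 0.3), recovers ~98% of planted switches.
- The enrichment z statistic is mildly anti-conservative (see §3); treat
  z values near the 1.96 boundary, rare-hit cells and degenerate-null
  cells as screening output, not final calls.
- Uniform-background sequences, independent events, and exponential
  survival are simplifications; the generator is designed to make the
  statistics testable, not to imitate genomic sequence structure.
- p-values from the normal/χ² branches are approximations whenever the
  exact-path size limits are exceeded; the limits are set where the
  approximations were verified to agree with enumeration.
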