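# spliceshift

Splicing-level analysis of a two-condition RNA-seq perturbation study,
modeled on the question "what happens to the transcriptome when a
transcription factor that also shapes splicing is silenced?": isoform-switch
detection, differential alternative-splicing calls, RNA-binding-protein
(RBP) motif enrichment around regulated events, and association of event
inclusion with marker expression, patient groups and survival in an external
cohort. A synthetic-data module generates every pipeline input with known
ground truth, so each statistical claim the package makes is testable
against planted signal.

## The scientific problem

Silencing a master regulator (here: unliganded estrogen receptor α in a
breast-cancer cell line) changes not just *how much* genes are expressed but
*which isoforms* they produce. Detecting that requires four linked analyses:

1. **Isoform switches** — within each gene, which isoforms gain usage and
   which lose it after silencing? Usage is the isoform fraction
   IF = TPM_isoform / TPM_gene; an isoform switches when its condition
   difference dIF is significant (Welch test on replicate IFs, BH-adjusted
   p ≤ 0.05) and substantial (|dIF| ≥ 0.1). Switch pairs are annotated with
   functional consequences (ORF/UTR length, domains, NMD sensitivity,
   coding status) and classified into splicing-event types from their exon
   structures.
2. **Differential splicing events** — for local alternative-splicing events
   (exon skipping ES, intron retention IR, alternative 5′/3′ splice sites
   A5/A3, mutually exclusive exons MX), inclusion is quantified from
   junction reads as length-normalized PSI (percent spliced-in) and tested
   per event (Welch on arcsine-√PSI, BH), flagged at |dPSI| ≥ 0.05 and
   adjusted p ≤ 0.05.
3. **RBP motif enrichment** — are known RBP binding motifs over-represented
   in and around regulated events, relative to events that did not change?
   Sequences are scanned FIMO-style with exact PWM score p-values; observed
   hit counts are compared to 100 resampled control sets of non-regulated
   events (matched in set size, region type, event type and length), and a
   (motif × region × direction) cell is called enriched when z > 1.96.
4. **Cohort association** — do the regulated events matter in patients?
   Event PSI is correlated with marker-gene expression (Spearman, exact for
   small n), compared across tumor/normal and marker-high/low groups
   (rank-sum), and tested for survival association by median-PSI split with
   Kaplan–Meier curves and log-rank tests.

## Library shape

The package follows the statsmodels convention: each analysis is a Model
class whose `fit()` returns a Results object with a `summary()` string and
tidy DataFrame attributes.

```python
from spliceshift import (SimulationConfig, simulate_ase_counts,
                         DifferentialSplicingModel)

cfg = SimulationConfig(seed=1)
events, truth = simulate_ase_counts(cfg)
cond = {f"{c}_{i}": c for c in ("control", "silenced") for i in (1, 2, 3)}
res = DifferentialSplicingModel(events, cond).fit()
print(res.summary())
```

```
Differential splicing (Welch on arcsine-root PSI, BH)
  events in:            203
  events after filter:  198
  significant events:   22 (|dPSI| >= 0.05, adj p <= 0.05)
  fraction dPSI > 0:    0.64
  ES      13  (59%)
  IR       5  (23%)
  A5       2  (9%)
  A3       1  (5%)
  MX       1  (5%)
```

All 22 significant calls at this seed are planted events with matching
signs; `truth` carries the planted dPSI per event for comparison.

## Worked example: the full CLI pipeline

Every stage is a subcommand of the `spliceshift` CLI and is byte-stable
under a fixed seed. Generate a complete synthetic study and run all four
analyses:

```bash
spliceshift simulate --seed 1 --outdir sim
spliceshift switch --iso sim/iso_tpm.tsv --samples sim/samples.tsv \
    --annotations sim/annotations.tsv --out switch
spliceshift ase --events sim/events.tsv --samples sim/samples.tsv --out ase
spliceshift motifs --fasta sim/regions.fa --meta sim/regions.tsv \
    --ase ase/flagged.tsv --pwms sim/motifs.meme --out motifs
spliceshift cohort --cohort sim/cohort.tsv --events sim/events.tsv \
    --out cohort
```

Actual output of the `switch` stage at seed 1 (500 genes, 3 vs 3
replicates, 10% of genes carry a planted switch):

```
Isoform switch analysis (Welch test on replicate IF, BH)
  isoforms tested:      1291
  switching isoforms:   98 (|dIF| >= 0.1, adj p <= 0.05)
  switching genes:      49
  up/down pairs:        49
  orf_length         gain  29 / loss  18  frac 0.62  adj p 0.419
  utr5_length        gain  22 / loss  24  frac 0.48  adj p 1
  utr3_length        gain  23 / loss  24  frac 0.49  adj p 1
  n_domains          gain  22 / loss  17  frac 0.56  adj p 0.881
  intron_retention   gain  10 / loss   7  frac 0.59  adj p 0.881
  nmd_insensitivity  gain   9 / loss   3  frac 0.75  adj p 0.419
  coding             gain   2 / loss   7  frac 0.22  adj p 0.419
```

and of the `motifs` stage (motifs M000 and M001 are the two the generator
plants in regulated regions — both are recovered at the top of the list):

```
RBP motif enrichment (100 control sets, z > 1.96, scan p < 0.001)
  cells evaluated: 270
  enriched cells:  59
  enriched motifs: 9
  M000 ES/downstream_flank/up: z = 34.81 (13 vs 0.9 +/- 0.3)
  M001 ES/spliced_region/up: z = 29.92 (16 vs 1.7 +/- 0.5)
  M000 ES/upstream_flank/up: z = 28.97 (10 vs 0.9 +/- 0.3)
  ...
```

The `cohort` stage correlates event PSI with the marker, runs the three
group comparisons, and the log-rank survival screen; the generator plants a
hazard ratio of 2 on the first event, which comes out on top:

```
Cohort association
  events correlated with marker: 3 / 20
  events flagged in all three group comparisons: 2
  ES_0000 OS: log-rank chi2 = 16.24, p = 5.58e-05 (high n=93, low n=93)
  ...
```

## Reproduction

`scripts/acceptance.py` runs the whole pipeline at the default study scale
for a given seed and writes the headline quantities of every stage —
switch counts and planted-switch recovery, significant splicing events and
their sign balance, enriched motif cells, cohort correlations and the
planted survival p-value — as a single JSON file:

```bash
python scripts/acceptance.py --seed 1 --out results.json
```

It finishes in well under a minute on one CPU. Rerunning with the same
seed reproduces the file exactly; `tests/test_acceptance.py` additionally
checks the statistical guarantees (exact PWM null, enrichment calibration
and recovery, switch and survival recovery, small-sample oracles, and
byte-level determinism of the CLI) and the full suite runs in ~7 minutes.

See `docs/methods.md` for the statistical model, generator design and the
reasoning behind every default.
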