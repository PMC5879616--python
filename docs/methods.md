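# Methods

## The model

`memtype` analyses the repeated-stress design C1 → D1 → R1 → D2: a naive
control, a first stress, a recovery that restores the physiological
baseline, and a second stress.  Transcriptional memory is defined
operationally on two contrasts.  The first contrast (D1 vs C1) asks whether
a gene responds to stress at all; the second (D2 vs D1) asks whether its
level moves *again* in the second stress.  A gene that responds and then
moves again ([+/+], [+/−], [−/+], [−/−]) carries memory; a gene that
responds once and repeats that level ([+/=], [−/=]) does not; a gene silent
in the first stress but responsive between D1 and D2 ([=/+], [=/−]) is a
late responder; [=/=] genes are non-responders.  The nine types partition
the detected-gene universe by construction, which the summary accounting
relies on (type counts sum to the total; the four categories likewise).

The per-stress Venn view ("up in D1" vs "up in D2") is computed against the
*control*: the second member is the D2-vs-C1 contrast, not D2-vs-D1.  This
is deliberate — if both Venn sets were the classification contrasts, the
intersection of up-sets would equal the [+/+] set identically and the
overlap accounting would be vacuous.  With D2-vs-C1 the [+/+] genes are a
proper subset of the common up-set, which matches how such overlaps are
reported (e.g. a [+/+] count amounting to ~26% of the common up-set).  The
Venn pair is configurable.

## DEG criterion

A direction call in {+, −, =} needs all three of:

1. **FDR**: BH-adjusted q ≤ `q_threshold` (default 0.05, inclusive).
2. **Effect size**: `log2FC = log2((mean_B + c)/(mean_A + c)) ≥
   fc_threshold` for "+" (or ≤ −threshold for "−"), pseudocount `c = 1`
   FPKM by default.  The pseudocount keeps genes that are off in one
   condition finite and is configurable.
3. **Expression floor**: the replicate-mean FPKM on the *up-regulated side*
   of the contrast (condition B for "+", condition A for "−") must be at
   least `floor_fraction` (default 20%) of the mean FPKM of all *expressed*
   genes in that condition.  "Expressed" means replicate-mean FPKM > 0 in
   at least one condition of the whole design; that gene universe is fixed
   across conditions so the floor varies only through the per-condition
   mean.  For the D2-vs-D1 contrast the "control side" of a down-call is
   D1, the baseline of that contrast.

All thresholds are inclusive: a gene at log2FC exactly 1.0 with q exactly
0.05 sitting exactly on the floor is called.  Replicates are aggregated by
arithmetic mean on the FPKM scale.

## P-value engines

The upstream count-model engines (Cuffdiff and kin) are not reproduced;
their output can be ingested verbatim (`method="precomputed"`, q recomputed
by BH when missing).  Two self-contained engines are provided:

* **Pooled z (default).**  On `log2(FPKM + c)`, within-condition residuals
  of *all* genes are pooled into one variance estimate (degrees of freedom
  ≈ genes × (replicates − 1) × 2), and each gene's mean difference is
  referred to a normal distribution.  This is the standard device for
  two-replicate RNA-seq designs: a per-gene test at n = 2 + 2 has one
  degree of freedom per group and no power — in particular an exact
  permutation test's smallest achievable two-sided p is 2/6 ≈ 0.33, so no
  gene could ever clear q ≤ 0.05.  Pooling assumes roughly homoscedastic
  log-scale noise across genes, which holds for the synthetic generator by
  construction and approximately for FPKM data after log transform; with
  many replicates and strong per-gene variance heterogeneity the
  permutation engine is the safer choice.  When the pooled variance is
  exactly zero (noise-free data) the p-value degenerates to the indicator
  of equal means.
* **Permutation.**  Per gene, the absolute difference of group means of
  `log2(FPKM + c)` under all reassignments of condition labels; exact
  enumeration up to 10 total replicates (e.g. all C(4,2) = 6 splits at
  2 + 2), seeded Monte-Carlo with the add-one estimator `(1 + hits)/(1 + B)`
  beyond.  Ties are counted with a 1e-12 absolute guard.

Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest.multipletests`; the test suite checks it
against an independent from-definition implementation.

## Enrichment

Term enrichment is a one-sided hypergeometric upper tail
`P[X ≥ k]` with `X ~ Hypergeom(M = |universe|, K = |term ∩ universe|,
n = |selected|)`, BH across terms.  Terms are flat gene sets (GMT); no GO
DAG propagation or pathway topology.  Terms with zero overlap are reported
with their computed tail (1), not dropped.

## Cross-species conservation

Conservation is classified per ortholog *pair* (many-to-many maps allowed;
an A gene with three orthologs contributes three records), restricted to
pairs whose A-side gene is a memory gene.  The category comes from the
B side: same memory type → conserved-same-type; other memory type →
memory-different-type; otherwise the B gene's own category, with genes
absent from the B assignment treated as non-responding.  The summary
reports every percentage with its explicit numerator and denominator,
including two per-type views keyed by either side of the pair — published
conservation figures mix both perspectives (the share of memory orthologs
carrying a given A-side type, and the per-B-type fraction that exactly
matches the A side) and neither denominator is usually printed.  A
secondary per-gene rollup marks an A gene conserved if *any* ortholog
shares its type.

## ΔΔCt and persistence

Classic ΔΔCt with amplification efficiency fixed at 2 and no
standard-curve correction: technical replicates averaged on the Ct scale,
ΔCt = Ct(target) − Ct(reference) per biological replicate, ΔΔCt against the
mean ΔCt of the calibrator condition, RQ = 2^(−ΔΔCt).  Because RQ is
log-normal by construction, biological replicates are aggregated on the
log2 scale (geometric-mean RQ, SD in log2 units), which makes the
calibrator's RQ exactly 1 and gives the exact identity that adding c
cycles to one sample's target Ct divides its RQ by 2^c.

Memory persistence after replanting is tested per interval by Welch's
two-sample t on per-replicate log2 RQ, trained plants' second stress vs
untrained plants' first stress; p ≤ 0.05 reads "memory-retained", otherwise
"baseline", with fewer than two biological replicates yielding
"insufficient-replication".  A two-group Welch test was chosen over a
multi-group multiple-range procedure: each interval is a self-contained
two-sample question, and the verdict should not depend on which other
intervals were assayed.  How technical and biological variability combine
into error bars is a reporting choice, not something recoverable from Ct
tables; here technical replicates are averaged first and only biological
variation enters the SD and the test.

## Physiology

RWC% = (fresh − dry)/(turgid − dry) × 100; weights violating
dry ≤ fresh ≤ turgid return a flagged (not raised) value for QC,
turgid = dry is an error.  Water loss is (w₀ − w(t))/w₀ over a detached-leaf
weight series with strictly increasing time; non-monotone loss (leaf
rehydration artifacts) is flagged per point.

## Synthetic data

The generator is the package's test bed and defines its study conditions:
four conditions × 2 biological replicates, baseline log2-FPKM ~
Normal(4, 1.5²) (median ~16 FPKM with a realistic dynamic range), planted
per-contrast effect Δ = 3 log2 units, replicate noise 0.25 log2 units
(log-normal FPKM noise).  Class [a/b] is planted through condition means:
D1 = C1 + aΔ, D2 = D1 + bΔ (a, b ∈ {+1, 0, −1}·Δ), R1 at the C1 level.

Two details matter:

* **Floor consistency.**  A low-baseline gene can satisfy its planted sign
  pattern yet fail the expression floor or the pseudocount-shrunk
  fold-change threshold.  The generator iteratively lifts such profiles
  (a constant on the log2 scale, preserving planted deltas and planted
  equalities) until every planted call holds under the criteria at zero
  noise, with a 1-log2 clearance margin beyond both thresholds so lifted
  genes do not sit exactly on a boundary where replicate noise would flip
  them half the time.  Planted classes are meant to be unambiguous;
  threshold-boundary behaviour is exercised by dedicated exact fixtures
  (`boundary_contrast_fixture`) instead.
* **What is and is not emulated.**  Noise is homoscedastic log-normal; real
  FPKM data has mean–variance structure, per-gene dispersion, and
  library-level effects the generator deliberately omits (the pipeline
  consumes FPKM, so count-level simulation would add realism the classifier
  never sees).  Passing recovery tests therefore demonstrates the
  correctness of the calling/classification logic under its stated
  assumptions, not robustness to dispersion misspecification — for real
  data with many replicates, the permutation engine or a precomputed
  count-model contrast is the appropriate route.

Ortholog maps are wired pair by pair: with the configured conservation
rate the B gene is drawn from the same type, otherwise the pair's category
is drawn from configured proportions (defaults dominated by non-responding
orthologs, as observed in real cross-species comparisons).  qPCR tables
plant a trained-vs-untrained log2 effect per gene, scaled by a per-interval
decay schedule, with biological (0.15) and technical (0.05) Ct noise and a
reference gene constant up to technical noise.

All generators are pure functions of (config, seed).

## Problem sizes and numerical choices

The test suite and acceptance script run at 200 genes per class
(1800 genes), 2 replicates, 20 seeds for the noisy-recovery average, and
three-replicate qPCR fixtures — sizes at which every quantity of interest
is stable while the whole suite runs in seconds.  The persistence reading
in the acceptance script is the median over 11 independent simulated
experiments: a single three-replicate assay of a 5% residual effect
occasionally reaches significance, and the median is the honest summary of
what the instrument reports.  Percentages are rounded half away from zero
at the precision of the figure they correspond to (integer for type
shares, 1–2 decimals for ratios).  Ties at call thresholds are inclusive
everywhere.

## Known limitations

* The pooled-variance default assumes exchangeable log-scale noise across
  genes; it will be anti-conservative for genes with unusually high
  biological variability.
* No missing-value handling in expression matrices (pre-impute or the
  reader errors), no library-size renormalisation, no batch correction.
* Enrichment treats annotation terms as flat sets; GO hierarchy effects
  are the caller's responsibility.
* The conservation analysis takes ortholog maps and second-species calls
  as inputs; no homology inference is performed.
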