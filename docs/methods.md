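# Methods

## The scoring problem

A chemogenomic knockout screen compares guide abundances between a
drug-treated and a control pool grown from the same library infection. Two
gene properties move a guide's treated/control ratio:

1. a genuine drug × gene interaction (the signal), and
2. the gene's fitness cost in the untreated condition (essentiality),
   whenever the two arms traverse different numbers of population
   doublings — which they always do, because the drug inhibits growth.

Under exponential growth, a guide with per-doubling log2 growth deviation
φ changes its log2 relative frequency by ≈ φ·D after D doublings. With
D_t < D_c, an essential, non-interacting gene (φ < 0) gains
φ·(D_t − D_c) > 0 in treated-vs-control log-ratio — it masquerades as a
suppressor. The scoring procedure therefore judges each gene against
*similarly essential* genes rather than against the whole library.

## Rank statistic

Guide score: rank all N library guides by log2((treated_cpm + ε)/(control_cpm + ε))
(ε = 0.5 CPM pseudocount, configurable; midrank ties), map rank r to the
quantile q = r/(N+1), and score s = ln(q/(1−q)). The log-odds transform is
symmetric about the median, unbounded in both tails, and — being purely
rank-based — invariant to any library-wide monotone transform of the
ratios and to sequencing depth. Gene score = mean of its guides' scores.

Empirical p-value: R pseudo-genes (default R = 9,999) are built by
sampling k guides without replacement from guides targeting *other* genes
in the gene's essentiality bin; two-sided p = (1 + #{|null| ≥ |obs|})/(1 + R),
so p ≥ 1/(1+R) and is never 0. Without-replacement sampling is implemented
by rejection (redraw index rows containing duplicates) — i.i.d. draws
conditioned on distinctness are exactly uniform over k-subsets, and the
method vectorizes, which keeps genome-scale scoring at seconds per screen.
If a bin holds fewer than 5k eligible guides the pool widens symmetrically
to adjacent bins (logged). Per-gene RNG streams are spawned from the run
seed keyed by sorted gene order, so results are independent of iteration
order and bit-reproducible.

## Essentiality matching, and where the bins come from

Genes are assigned to 20 contiguous quantile bins (configurable) of an
essentiality score, lower = more essential. Twenty bins keep the matching
fine enough to track depletion behavior while leaving, at genome scale
(~20k genes × 10 guides), on the order of 10⁴ guides per bin for the null
pool.

The *source* of the score matters. The preferred source is a prior,
screen-independent essentiality ranking of the same cell line (such
rankings exist for common lines from earlier genome-wide fitness screens);
`score --essentiality` accepts any gene → score TSV. The fallback — the
gene-mean log2 control-arm abundance of the current screen — is supported
but mildly conservative: the gene's own guides enter both its bin
assignment and its log-ratio, so conditioning on the bin constrains the
observed score's control-noise component while null-pool guides retain
their full within-gene variance. On a pure-noise screen this inflates the
null by roughly √(2 − 1/k) and drops the empirical false-positive rate at
α = 0.05 to ≈ 0.02. The simulator therefore emits an `essentiality_prior`
per gene — the planted fitness scaled by the gene's realized mean guide
efficiency plus N(0, 0.05) measurement noise — emulating the earlier
independent screen a real analysis would use; the calibration and
confound analyses use it.

## Generative model of the simulator

For each arm of each screen:

1. start all n guides at bottleneck_cells/n cells (uniform infection);
2. per-guide deviation φ_g = efficiency_g × (fitness_gene +
   interaction_effect_gene·1[treated]), log2 per doubling;
3. deterministic exponential growth, 2^((1+φ_g)·d) per passage interval,
   with D_arm doublings split evenly over n_passages intervals;
4. multinomial resampling to bottleneck_cells at every passage except the
   last (genetic drift from reseeding);
5. final multinomial read-out with reads_per_sample trials, so column sums
   equal the configured depth exactly.

Defaults, chosen once as a realistic screen configuration: control arm 8
doublings (one per day over an 8-day exposure), treated arm 5 (strong but
partial growth inhibition; per-screen values configurable), 4 passage
intervals (reseeding every ~2 days), bottleneck 100 cells/guide, depth 100
reads/guide, 10 guides/gene, 20 % essential genes at fitness −0.3 log2 per
doubling (≈ 5-fold depletion over the screen), guide efficiency ~
Beta(5, 1) (mean 0.83, reflecting frequent partial/heterozygous editing;
β = 0 is accepted as "all efficiencies exactly 1" for closed-form
checks). Planted enhancers/suppressors receive interaction effects
∓|interaction_effect| and are placed on non-essential genes, so recovery
measures interaction detection rather than essentiality. Multiple screens
share one truth (same library, fitness and interactions) and differ only
in their RNG streams and optional per-screen doubling gaps — emulating
screens of the same library against different compounds.

What the simulator does *not* model: Cas9-induction kinetics, cell-cycle
mechanism, guide-sequence-dependent off-target effects, PCR jackpotting or
explicit overdispersion beyond the bottleneck (drift through reseeding
already produces super-multinomial variance), and real screens' uneven
initial library representation. Passing tests therefore demonstrate the
statistics under a faithful growth-and-sampling model, not robustness to
every artifact of real data.

## Multi-screen integration

Mean score across screens sets direction; Fisher's method combines the
per-screen empirical p-values (χ² = −2Σln pᵢ on 2k df, k = screens where
the gene was scored — missingness reduces df rather than imputing);
Benjamini–Hochberg converts combined p to FDR. Fisher's method assumes
independent screens; different-compound screens of one library share the
infection and library composition, so this is an approximation, adopted
deliberately and flagged here. Screens disagreeing on sign are combined by
the mean but flagged in a `discordant` column. Hit classes: enhancer
(mean < 0) or suppressor (mean > 0) at FDR < 0.05 for reporting; the
network test conventionally takes the stricter FDR < 0.001 set.

## Network and gene-set significance

Hub hits with ≥ 200 partners are removed from both the hit list and the
graph before anything else — a single promiscuous protein would otherwise
dominate both the observed count and the null. Observed statistic: unique
edges with both endpoints in the hit set. Null: every stub (interaction
partner slot) of every hit is redirected independently to a node drawn
with probability ∝ degree; the statistic counts replacements that are
hits. This preserves the degree sequence in expectation and has the exact
closed-form mean D_H²/D_total, used as a cross-check in tests. Note the
asymmetry: a hit–hit edge contributes two stubs to the null but one count
to the observed statistic, making the test conservative for dense hit
subgraphs; `variant="edge"` (each hit-incident edge redirected once) is
provided for sensitivity analysis. Empirical p uses the add-one rule.

Gene-set over-representation: one-sided hypergeometric upper-tail p per
term on the 2×2 table (overlap, hits∖term, term∖hits, rest) against the
declared universe, BH across terms; terms with no universe overlap are
skipped.

## Numerical and degenerate-input choices

* p-values are validated into (0, 1]; p = 0 is rejected (cannot arise from
  add-one empirical p-values).
* Quantile binning uses `qcut`; fully tied scores collapse to one bin with
  a warning (matching then degenerates, correctly, to a library-wide null).
* Guides missing from a counts file get zero counts with a warning
  (dropout is expected); negative, fractional or unknown-guide entries are
  hard errors with cell coordinates.
* Lane pooling groups on (screen, arm, compound, concentration,
  timepoint); control pooling sums all control samples and timepoints of a
  screen regardless of solvent. Both conserve the grand total read count.
* Self-loops in network input are dropped (node retained at degree 0 by
  default — degree-0 nodes cannot be drawn by the shuffle and are
  harmless); duplicate edges in either orientation collapse.
* Sorting everywhere uses stable mergesort, and all randomness flows from
  explicit seeds, so identical inputs give byte-identical outputs.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run the statistical checks at
1,000 genes × 10 guides + 100 control guides, with 999 resamples per gene
(p-value granularity 10⁻³, ample for calibration bands at α = 0.05),
10⁵ shuffles for the network-null checks and 3 screens for recovery —
sizes at which every distributional claim is well-powered while the whole
verification completes in well under a minute per analysis. The packaged
golden fixture (tests/data/golden) is a 40-gene, 2-screen simulation kept
small enough to ship as plain text; it is bit-regenerable from its
recorded config, which the tests assert.

## Known limitations

* The matched null conditions on binned essentiality only; residual
  within-bin heterogeneity (e.g. very unequal fitness inside a bin) leaves
  a small amount of miscalibration, bounded in practice by bin width.
* Own-control essentiality binning is conservative (see above); use an
  external ranking when one exists.
* Fisher combination treats screens as independent (see above).
* The degree-proportional stub null is the configuration-model
  approximation; it does not forbid multi-edges or self-replacements, and
  for hit sets covering a large fraction of total degree its normal-range
  behavior differs from an exact edge-swap null.
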