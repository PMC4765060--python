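# Methods

This note documents the models and procedures `bigih` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Selection of changed genes

Fold changes are signed ratios of arithmetic group means: for a side
with mean `m` and naive mean `m0`, the signed fold change is `m/m0` when
that ratio is ≥ 1 and `−m0/m` otherwise, so the codomain excludes
(−1, 1). Arithmetic means are used because they are deterministic,
order-independent and the natural estimator for intensity-scale
replicates; no per-gene variance model is fitted and no statistical test
accompanies the cutoff — the workflow is deliberately a fold-change
filter.

A gene counts as changed on a side when `|fc| ≥ fold_change_cutoff`
(default 2; exactly 2-fold counts, "2-fold or more") and the presence
gate holds. The gate is shared between sides: a present call in **all**
ipsilateral samples *or* **all** contralateral samples admits the gene
on both sides. Marginal calls do not count as present. Presence in the
naive group is not required; requiring it would bias against genes
switched on by the injury. The cutoff comparison carries a `1e−12`
relative tolerance so genes sitting exactly on the boundary do not flip
on float rounding of replicate means.

Duplicate gene rows in input expression tables are collapsed by
arithmetic mean (with a warning): deterministic and order-independent,
though it ignores probe-set quality differences a platform-aware
summarization would exploit.

## Detection calls

Each probe pair contributes a discrimination score
`R = (PM − MM)/(PM + MM) ∈ [−1, 1]`; pairs with zero total intensity are
excluded with a warning. The call tests `H1: median(R) > tau` with a
one-sided Wilcoxon signed-rank test: `p < alpha1` → present,
`alpha1 ≤ p < alpha2` → marginal, otherwise absent. Defaults
`tau = 0.015, alpha1 = 0.04, alpha2 = 0.06` follow common single-array
detection practice (they are conventional values, not fitted here) and
are configurable.

The signed-rank p-value is computed exactly for up to 20 pairs by
convolving the null distribution of the positive-rank sum over all sign
assignments, working on doubled midranks so tied |differences| (common
when many probe pairs saturate) stay in integer arithmetic. Zero
differences are dropped (standard Wilcoxon treatment); if all
differences are zero the call degenerates to absent with p = 1 and a
warning. Beyond 20 pairs a tie-corrected normal approximation with
continuity correction is used. The exact path is implemented in-package
because library routines for the exact distribution do not admit ties.

Probe-set summarization itself (robust signal averaging, background
zones, between-array scaling) is out of scope; the pipeline consumes
summarized expression values, and the probe-level stage is an optional
entry point.

## Bilateral ratio and partition

With `lin(f) = f` for `f > 0` and `1/|f|` otherwise, the ratio of a pair
`(f_i, f_c)` is `r = lin(f_i)/lin(f_c)`, reported as `r` when `r ≥ 1`
and `−1/r` otherwise. On each of the five sign/order regimes that a
piecewise formulation distinguishes (both up with ipsilateral larger;
both down, either side more suppressed; opposite directions both ways)
this reduces algebraically to the corresponding piecewise formula — a
property-based test checks the equivalence on random pairs per regime.
The sixth regime, both sides increased with the contralateral change
larger, is not covered by the piecewise list; the generalized rule
handles it by the same symmetry (yielding a negative ratio) and such
rows are flagged `extrapolated` in output.

"Changed differently" means `|ratio| > ratio_cutoff` (default 2,
strictly greater). The magnitude is used because negative-ratio genes
(relative expression lower ipsilaterally) belong in the
changed-differently class on any consistent reading: among the 73
bundled reference pairs, three (DNAJB6, TRIM54, PSIP1) have negative
ratios. Output tables round ratios to 3 decimals; internal values keep
full precision.

## Genes of interest and accounting

The candidate pool for a side is the union of that side's uniquely
changed genes and all changed-differently genes. Sources are processed
in a fixed order — canonical pathway first, then networks by ID — and
each contributes `members ∩ pool` (when the caller supplies lists that
are already the overlap, no pool is applied). Accounting is computed
against the running union, seed first, so for every source
`overlap_with_previous + net_new = total_found`, and the net
contributions plus the seed size telescope to the final set size. The
final gene set is provably order-independent (set union); only the
accounting depends on order, and a property test exercises both facts on
random source configurations.

Gene identity is the uppercased trimmed symbol with trailing
parenthesized aliases removed. No alias or orthology resolution is
attempted: the bundled tables are symbol-keyed, and resolving families
(e.g. an "Hsp70" group node) to member genes is the data curator's
responsibility, not the pipeline's.

## Interaction hierarchy

Edges are undirected and unweighted; interaction type and direction are
discarded, and self-loops are removed on input. Connection counts are
degrees in the GOI-induced simple graph — distinct neighbors, self
excluded, duplicate/antiparallel input edges counted once — verified
against brute-force neighbor enumeration on random graphs.

Tier cutoffs derive from the main component (largest connected
component; ties broken by smallest lexicographic member for
deterministic output) of size `n`:

* primary: connections > `round_half_up(0.10 · (n−1))`
* secondary: connections ≥ `ceil(0.05 · (n−1))` and ≤ the primary cutoff
* peripheral: at least 1 connection below the secondary minimum
* orphan: 0 connections.

Round-half-up for the primary cutoff and ceiling for the secondary
minimum is the only simple integerization consistent with both reference
instantiations of the verbal 10 %/5 % rule (n = 145 → >14 and ≥8;
n = 78 → >8 and ≥4; note 10 % of 77 is 7.7, so a plain "more than 10 %"
reading would give >7, contradicting the published >8). Both fractions
are configurable. An epsilon of 1e−9 guards the integerization against
float fuzz in `fraction · (n−1)`.

Connected nodes outside the main component are tiered by the same
thresholds and flagged `off_main_component` rather than merged into the
orphans: hiding them would misstate their connectivity.

## Enrichment and cross-referencing

Function association is the hypergeometric upper tail with the observed
overlap included (right-tailed Fisher exact test), computed through the
standard hypergeometric survival function and verified against
exhaustive enumeration for small universes. The universe defaults to
all measured genes and is user-overridable; curated commercial tools
use proprietary knowledge-base universes, so absolute p-values are
comparable only within a run — rankings, not significance calls, drive
the analysis. Ties in p are ordered by descending overlap then name. A
named seed-function exclusion (the function the genes were selected by)
is a config option, not hard-coded. No multiple-testing correction is
applied by default; Benjamini–Hochberg q-values are available.

Rank shifts between two rankings are `rank_before − rank_after`
(positive = moved up); functions present in only one ranking are flagged
rather than assigned a shift. Tier cross-referencing reports, per tier,
the annotated members with up/down fractions by fold-change sign, plus
the top-two-tier aggregate.

## qPCR relative quantification

Each well's `ΔCt = Ct(target) − Ct(reference)`; each experimental
replicate is compared against the **mean** naive ΔCt
(`value = 2^−(ΔCt − mean ΔCt_naive)`), the standard implementation when
replicates are unpaired, with mean ± standard error over replicates.
Amplification efficiency is fixed at 2 per cycle (no efficiency
correction), giving the shift-invariance and one-cycle-doubles
properties the tests assert. Group comparisons use the pooled
(equal-variance) t statistic with `n_a + n_b − 2` degrees of freedom and
a one-tailed p for the stated direction; zero pooled variance with equal
means degenerates to p = 0.5 with a warning.

## Synthetic benchmark

The generator emulates the features the pipeline's logic depends on:

* 3 replicates per group (ipsilateral, contralateral, naive) over
  log-normal baselines (log-mean log 500, log-sd 1) with multiplicative
  log-normal replicate noise (sigma 0.05 by default);
* side-biased differential expression: 18 % of genes uniquely
  ipsilateral (88 % up), 6.8 % uniquely contralateral (75 % down), 20 %
  on both sides with 82 % changing similarly — the proportions of the
  study design the defaults reproduce — with fold-change magnitudes
  log-uniform on [2, 40] (bounded and heavy-tailed, comfortably inside
  the reference tables' ~2–83 range while keeping ratios finite);
* a preferential-attachment interaction graph (m = 2) over the GOI plus
  300 background genes, with 3 planted hubs each wired to 25 % of the
  other GOI so their induced degree clears the primary cutoff (≈10 % of
  the main component) by better than 2×;
* random annotation sets plus one focal set enriched among the hubs
  with configurable strength.

All randomness flows from one root seed fanned out per sub-generator via
seed sequences; fixed seed ⇒ identical outputs. Detection calls are
emitted directly (present, with configurable dropout) rather than via
simulated probe pairs; the Wilcoxon stage has its own unit-level inputs.

What passing synthetic tests shows: the pipeline's algebra and graph
logic recover planted structure under the stated noise model —
partition classes exactly at zero noise, direction biases within
binomial error at the default 2000 genes, planted hubs in the primary
tier in ≥95 % of 200 seeded runs. What it does not show: robustness to
array artifacts, batch effects, probe-sequence biases, normalization
error, or the adequacy of any particular curated interaction network —
real interaction knowledge bases are neither random nor
preferential-attachment graphs, and published tier memberships depend
on the specific edge set used.

## Problem sizes and runtime

The default test suite simulates at 300–2000 genes, uses random graphs
of ≤160 GOI plus ≤300 background nodes, enumerates Fisher tails for
universes ≤ 25 and signed-rank nulls for ≤ 12 pairs against oracles, and
repeats the hub-recovery experiment over 200 seeds; the whole suite runs
in a few seconds on one CPU, and `scripts/acceptance.py` likewise.

## Known limitations

* Symbol-keyed identity: cross-species or alias-divergent inputs must be
  harmonized upstream.
* The presence gate assumes detection calls are supplied (or trusted to
  be all-present); no call imputation is performed.
* The hierarchy is purely degree-based by design; no centrality measure
  beyond first-order connections is computed, mirroring the method it
  implements.
* Enrichment p-values depend on the chosen universe; only within-run
  rankings are meaningful.
* With two replicates per group, qPCR t-tests have a single degree of
  freedom per group pair; results should be read as descriptive.
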