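# Methods

This note documents the models, parameter choices and numerical decisions
behind `paleoks`, and what the synthetic-data tests do and do not
demonstrate about real genomes.

## Ks estimation (NG86)

Per-pair Ks/Ka uses the Nei–Gojobori (1986) counting method on a
protein-guided codon alignment:

- **Sites.** For each sense codon, each of the nine single-nucleotide
  neighbours is classified against the standard genetic code; position
  *i* contributes `s_i = (#synonymous changes at i)/3` synonymous sites,
  and `S + N = 3` per codon exactly. Changes to stop codons count as
  nonsynonymous. Site totals are averaged over the two sequences.
- **Differences.** For a codon pair differing at *k* ≤ 3 positions, all
  *k*! orderings of single-nucleotide steps are weighted equally; a step
  is synonymous when both endpoints are sense codons encoding the same
  amino acid. `Sd + Nd` equals the nucleotide Hamming distance by
  construction.
- **Correction.** `Ks = −(3/4)·ln(1 − (4/3)·pS)` (Jukes–Cantor) with
  `pS = Sd/S`; the estimate is flagged undefined when `pS ≥ 3/4`
  (saturation). Columns containing gaps, ambiguity codes or stop codons
  are excluded from counting, not end-trimmed.

The estimator is deliberately simple and fully specified: no
transition/transversion weighting and no codon-frequency correction
(these belong to ML codon models, out of scope). Because the downstream
analysis consumes *peak locations* and the rate correction is a per-species
scalar, a monotone shift between NG86 and a likelihood estimator is
absorbed by the correction stage. External Ks tables can be supplied
through `formats.read_ks_table` when exact reproduction of another
estimator's values is needed. Protein alignments are inputs (aligning is
upstream); `backtranslate` validates that each CDS translates to its
ungapped protein and threads codons onto alignment columns.

Equivalence with an independent exhaustive path-enumeration oracle over
all sense-codon pairs, and with Biopython's NG86 implementation on
simulated pairs, is asserted in the test suite.

## Block medians and peak fitting

Pair-level Ks distributions have long right tails (saturated estimates,
tandem/allelic pairs near zero). The fitting unit is therefore the
**median Ks of each collinear block**. Pairs are windowed to
`(0.05, 4.0]` — the lower bound removes near-zero allelic/tandem pairs,
the upper removes saturated estimates — and blocks retaining fewer than
`min_pairs = 5` values are dropped. Both values are configuration keys;
they are conservative defaults, not published constants.

Per species, block medians are fitted with a K-component 1-D Gaussian
mixture where **K equals the species' known number of polyploidy rounds**
(model selection over K is intentionally out of scope; the polyploidy
history is an input). The EM implementation is deterministic:

- initial means at the `(i + 0.5)/K` data quantiles, initial standard
  deviations `SD(x)/K` (pooled start), uniform weights;
- convergence when the total log-likelihood improves by `< 1e-6`, capped
  at 500 iterations; variances floored at `(5e-5)²` for numerical safety;
- a degenerate component (σ < 1e-4 or weight < 0.01) triggers one refit
  from a seed-perturbed initialisation, then an error;
- components are reported sorted by mean, and the log-likelihood trace is
  kept so monotonicity is testable.

The event peak `P_q` is the fitted component mean (the mode of a
Gaussian), not a histogram argmax — so no bin width enters the analysis.
Event labels follow the event ordering: the highest-mean component is the
shared triplication ("ceWGT", the oldest event); younger components are
`WGD_1`, `WGD_2`, … in descending mean.

## Rate correction

For species *q* with ceWGT peak `P_q` and reference peak `P_ref`,
`C_q = P_ref / P_q` and `Ks′ = Ks · C_q`. Corrected peak models are
obtained by scaling fitted means and standard deviations — exact by the
linearity of the Gaussian family, so no refit is needed (a refit path
exists and is used as a validation property in tests). Consequences that
the tests assert: the reference is a fixed point (`C_ref = 1`), corrected
ceWGT peaks align to `P_ref` exactly, within-species peak ratios are
invariant, and the correction is idempotent. The reference species is the
metadata row flagged `is_reference` (configurable override), reflecting
that the choice of a slowly evolving, structurally conserved reference is
a biological judgement, not an algorithmic one.

## Event dating

- **Anchored:** `age = T_anchor · P_event / P_ceWGT`, with the ceWGT
  anchor interval 115–130 Myr. Being ratio-based, anchored ages are
  homogeneous of degree zero in the correction scalar — they can be
  computed from uncorrected peaks, and correction upstream matters only
  for cross-species displays.
- **Fixed-rate:** `age = Ks / (2r)` with `r = 7.0×10⁻⁹` synonymous
  substitutions/site/year. The divisor 2 reflects that both duplicate
  lineages accumulate substitutions since the event; this is the standard
  convention for paralog pairs.

Fit uncertainty (σ of the peak component) is reported but not propagated
into age intervals; the anchor interval width dominates.

## Comparative statistics

Percent rate differences put the slower (reference) lineage in the
denominator: `100·(P_fast − P_slow)/P_slow`. Group summaries use the
sample SD (n−1) and CV = SD/mean. The group test is **Welch's t**
(unequal variances) by default — the safer choice for unequal group sizes
— with a pooled-variance flag. The association between peak height and
polyploidy history is a **Pearson correlation** of ceWGT peak vs the
integer number of polyploidy rounds (a triplication counts as one round),
with the two-sided p-value from the t transform. Spearman would be an
equally defensible choice for an ordinal predictor; Pearson was fixed as
the default once and recorded here.

## Functional strata

Pairs are ranked by Ks; the top and bottom `⌈q·n⌉` pairs (q = 0.2) define
the fast and slow strata, and both genes of a selected pair inherit its
stratum. Two deliberate rules make this deterministic and conservative:
ties at the quantile boundary are resolved by gene-id lexicographic order
(the two strata take opposite lexicographic ends, so they stay disjoint
under heavy ties), and a gene reached by both strata through different
pairs is dropped from both, with the count reported. By default only
pairs inside the fitted ceWGT component's ±2.5σ window are ranked
(`scope = "ceWGT_pairs_only"`), since the strata concern ceWGT-derived
duplicates; `all_pairs` is available. Pathway categories are taken
verbatim from the annotation table (no ontology logic); a multi-category
gene counts once per category. The 2×K table is tested with Pearson's
chi-square without continuity correction, df = K−1, flagging tables with
any expected count below 5.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with ground truth saved alongside:

- **Ks datasets.** For species *q* and event *e* of age `T` Myr, the
  pair-level cloud is Normal(`μ`, `σ_Ks`) truncated at zero with
  `μ = 2·r·T·ρ_q` (`ρ_q` the lineage rate multiplier), contaminated with
  a 5% uniform background over the analysis window to emulate the long
  tails of real Ks distributions. Blocks receive Poisson(mean−1)+1 pairs.
  The default study design mirrors the analysis scale: 28 species
  (12 P1R, 16 P2R), ceWGT at 122.5 Myr (anchor midpoint), additional P2R
  WGDs uniform in 30–60 Myr, 500 blocks/event, ~8 pairs/block,
  `σ_Ks = 0.2`, planted P2R rate elevation +5%, and residual per-lineage
  log-normal rate jitter of 1.5% around the group mean. The jitter
  represents the lineage rate variation left *after* the planted group
  effect; it is intentionally smaller than real between-species variation
  (real P1R/P2R CVs are an order of magnitude larger) so that end-to-end
  tests measure pipeline error rather than irreducible sampling noise of
  a 28-species design.
- **Codon pairs.** One sequence is a random sense-codon ancestor; the
  other carries planted single-nucleotide substitutions, at most one per
  codon, each synonymous alternative chosen with probability `pS/3` and
  each nonsynonymous sense alternative with `pN/3`, where `pS`, `pN` are
  the divergence targets pushed through the Jukes–Cantor map
  `p = (3/4)(1 − e^{−4d/3})`. This construction makes the expected NG86
  Ks equal the target essentially exactly: saturation lives in the
  planted proportions, and a single change per codon is classified
  identically along every substitution ordering. An event-by-event
  simulation was rejected because synonymous changes at 2-fold-degenerate
  sites toggle between two states rather than three, so the Jukes–Cantor
  inversion over-corrects and the estimator is no longer centred on the
  nominal divergence (~2% low at Ks = 1) — the planted-proportion design
  is the one whose calibration is provable and testable. Its cost: no
  multi-hit codons in simulated pairs (multi-difference codons are
  covered directly by the exhaustive path-enumeration tests), and the
  nonsynonymous target is slightly underestimated because stop codons
  count as nonsynonymous sites but are never substituted into.
- **Annotations.** One category per gene, uniform over a fixed list;
  genes in the fast set get the enrichment category's odds multiplied by
  a configurable factor (default 3).

**What passing tests show — and do not.** The generator matches the
fitted model family (truncated-normal clouds per event), so recovery
tests demonstrate correctness of the estimation machinery, not robustness
to model misspecification. Real Ks distributions add fractionation and
gene loss, variable block sizes and breakpoints, overlapping events close
in time, GC-content and codon-usage effects on the estimator, and
annotation errors — none of which are simulated. The contamination option
stresses only the simplest form of tail misspecification.

## Problem sizes

Test and acceptance runs use sizes chosen to make Monte-Carlo assertions
sharp at desk scale: 20 replicates × 2,000 medians for peak recovery,
200 pairs × 500 codons per divergence target for estimator calibration,
1,000 null replicates for test calibration, and 20 seeded 28-species
datasets (~176k pairs each) for end-to-end recovery.

## Known limitations

- Component count must equal the known polyploidy rounds; lineages with
  unknown histories would need model selection (BIC/ICL), which is out of
  scope.
- NG86 underestimates Ks relative to ML codon models at high divergence;
  cross-species conclusions are protected by the scalar correction, but
  absolute fixed-rate dates inherit the estimator's bias.
- The correction assumes rate constancy *within* a lineage across the
  window spanned by its events (a single scalar per species).
- Anchored dates inherit the anchor interval entirely; no uncertainty
  propagation from the fit.
- Strata membership via pairs can drop genes under conflicting evidence;
  with heavy ties the lexicographic rule is arbitrary (but deterministic
  and disjoint).
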