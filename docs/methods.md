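# Methods

`stromaging` implements a small, fully specified analysis of age-related
expression differences in tumour-associated stroma: two-group signed
fold-change differential expression, a running-sum gene-set enrichment
statistic with an empirical permutation null, and direction-stratified
overlap of DE gene lists across datasets. This note records the model,
its assumptions, the numerical conventions, and the choices made where
the procedure was genuinely open.

## Input model and pre-processing

The analysis starts from a probe/gene × sample matrix of **log2-scale
normalised intensities** (e.g. fRMA output); normalisation is upstream
and out of scope. Samples carry a two-level age-group label, `young`
and `old`, each with at least two samples. When several probe sets map
to one gene symbol, their values are averaged per sample **on the log2
scale** (the scale the normalisation emits) and the matrix is re-indexed
by symbol, sorted lexicographically. Probes without a symbol annotation
are dropped: all downstream matching is symbol-based, so a sentinel
symbol would only create spurious "genes". The probe→symbol mapping is
an explicit input; the package bundles no annotation version. Duplicate
sample ids are a hard error (grouping would be ambiguous), and samples
absent from the group map are dropped with a logged warning.

## Signed fold change

For gene *g* with young-group log2 values *x* and old-group values *y*,
the default fold change is the ratio of linearised group means,

    r_g = mean(2^x) / mean(2^y),

reported as the signed value `r` if `r ≥ 1` and `-1/r` otherwise, so
|FC| ≥ 1 always and **negative FC means higher expression in the old
group**. "Fold change" is a linear-scale notion, which is why the group
means are linearised before the ratio; the geometric-mean alternative
`r = 2^(mean(x) − mean(y))` is available as `fc_mode =
"diff_of_log_means"` since the two conventions differ in real data and
published analyses do not always say which was used. A gene is called
differentially expressed when |FC| ≥ 1.5 (configurable; must exceed 1).
A two-sided Wilcoxon rank-sum p-value accompanies every gene but does
not enter the DE call by default — the fold-change rule is the sole
criterion, and no multiplicity adjustment is applied at this stage. An
optional `p_threshold` adds the p-value to the call for users who want
it.

Two boundary conventions worth knowing: a ratio of exactly 1 maps to
+1.0 in either group orientation (the signed codomain excludes (−1, 1),
so exact label-swap antisymmetry holds only for |FC| > 1), and the
Wilcoxon p is 1 by convention when every value in both groups is
identical. The Wilcoxon p uses the exact null when the pooled sample
size is ≤ 20 with no ties, and the tie-corrected normal approximation
with continuity correction otherwise.

## Enrichment score

Genes are ranked by signed fold change, descending: most up-in-young
first, most up-in-old last; exact ties break lexicographically by
symbol so the ranking is deterministic. For a query set intersected
with the ranked universe (N genes, n_hit of them set members), a
running sum is walked down the ranking:

* unweighted (default): +1/n_hit on a hit, −1/(N − n_hit) on a miss;
* weighted: +|score_i| / Σ|score_hits| on a hit, same miss decrement.

The enrichment score is the signed maximum-magnitude deviation of the
walk, in [−1, 1]; the unweighted walk ends at 0 exactly. Positive ES ⇒
the set concentrates among genes up in young; negative ES ⇒ up in old.
A single signed ES (rather than a max-positive/min-negative pair) is
reported per set. When the positive and negative excursions are exactly
equal — possible for symmetric hit placements in small universes — the
negative excursion is returned; the comparison carries a 1e-9 guard so
the choice does not depend on floating-point evaluation order.

The unweighted statistic is the default because it admits an exact
brute-force oracle (the test suite checks every instance with N ≤ 12
and set size ≤ 4 against a literal walk) and requires no weighting
exponent choice; the weighted variant (exponent 1 on |score|) is a
config switch. This choice matters when comparing against other
running-sum implementations, whose defaults are typically weighted.

## Permutation null and FDR

Significance is empirical and two-sided on |ES|:

* **gene-label scheme** (default): the ranking is fixed and `n_perm`
  random sets of size n_hit are drawn from the universe without
  replacement. The p-value is `(1 + #{|ES*| ≥ |ES|}) / (1 + n_perm)`,
  never 0 by construction. For tiny problems an exhaustive mode
  enumerates all C(N, n_hit) placements instead.
* **phenotype scheme**: sample group labels are shuffled, fold changes
  recomputed, the ranking rebuilt, and ES recomputed; statistically the
  stricter null (it preserves inter-gene correlation) but far more
  expensive, and with 9 + 8 samples the label-split space is itself
  limited. Sampled permutations only; full enumeration of the C(17,8)
  splits is deliberately not attempted.

The gene-label scheme is the default because the ranking is computed
once, the null is exactly specifiable, and its p-values are verifiably
uniform under a null generator (tested by Kolmogorov–Smirnov against
U(0,1)). Across the batch of tested sets, q-values are
Benjamini–Hochberg step-up adjusted (`statsmodels.multipletests`),
with q < 0.05 the significance convention. Sets overlapping the
universe in fewer than `min_hits` genes (default 3) are reported as
skipped rather than scored: with 3–5 hits the permutation p is already
very coarse, and below that it is close to meaningless. Every sampled
null requires an explicit seed (default 1); per-set child seeds are
spawned deterministically from it so results do not depend on which
other sets were skipped.

## Curated gene programmes

Four literature-curated sets ship with the package: cellular senescence
effectors (5 genes: CDKN1A, CDKN2A, TP53, RB1, GLB1), the DNA-damage
response axis (3: ATM, NBN, CHEK2), the senescence-associated secretory
profile (44 symbols), and the autophagy-to-senescence transition
("reverse Warburg") programme (15). Symbols are used exactly as
curated (e.g. IL8, not its alias CXCL8): matching is against the
expression platform's own symbol annotation, and silent alias
resolution would change set membership. CCL3 is carried as a
*provisional* secretome member — its curation was marked uncertain —
and is excluded from scoring by default; `include_provisional=True`
restores it. GMT serialisation keeps the flag by parenthesising
provisional symbols, so read(write(x)) is the identity.

## Cross-dataset overlap validation

Study DE genes are intersected with externally derived DE lists,
separately per direction (up-in-old / up-in-young), after restricting
all lists to the **intersection of the datasets' measured universes** —
the most conservative well-defined universe. Overlap significance is
the one-sided upper-tail hypergeometric probability P(X ≥ k), the
standard test for gene-list intersection. External lists are explicit
TSV inputs (symbol, direction, dataset id); the package does not
download or re-analyse external datasets, and the shipped
`external_lists_synthetic.tsv` is a synthetic stand-in containing the
ten validated genes, used for demos and tests.

## Synthetic-data generator

The generator draws gene baselines from Normal(7, 1) log2 units and
adds i.i.d. Normal(0, 0.3) residual noise per value — a deliberately
plain Gaussian model of normalised microarray data. Defaults mirror
the study design: 9 young vs 8 old samples, ~2000 genes. It can
inject (i) sparse strong DE genes (a ±`de_log2fc` shift in the old
group, random sign, default |FC| = 2), (ii) *modules*: designated sets
whose members all receive the same coordinated shift in one group —
sub-threshold by default, so set-level enrichment rather than
single-gene DE is what detects them — and (iii) many-probes-per-gene
redundancy, each probe jittered by Normal(0, noise_sd/2) around its
gene's profile. The ground truth (which genes, which direction, which
modules) is returned alongside the matrix and everything is
reproducible bit-for-bit from the seed.

What the generator does **not** model: probe-level platform noise,
intensity-dependent variance, inter-gene correlation outside injected
modules, sample quality gradients, or dissection/amplification
artefacts of laser-capture material. Passing tests on this generator
therefore demonstrate the statistics' correctness and calibration
under their own assumptions, not robustness to real microarray
pathology.

`null_battery` runs effect-free replicates through the whole stack and
reports observed type-I rates. Note that the exact rank-sum test at
n = 9 vs 8 is discrete: its attainable level at nominal α = 0.05 is
≈ 0.044, and the battery's observed rate should be compared to that
attainable level, not to α itself.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` use: exhaustive ES oracles
up to N = 12; Wilcoxon enumeration up to 8 pooled values; 500 (tests)
or 200 (script) null replicates of 200 genes at 200 permutations for
the uniformity check; 2000-gene studies with 10,000 permutations for
module recovery; and a 20-replicate null battery of 500 genes. These
sizes were chosen so every check runs comfortably on a laptop while
keeping Monte-Carlo standard errors well inside the asserted margins.

## Reproducing the published enrichment scores

The original study reports ES values of −0.21 (secretome), −0.42
(autophagy programme), −0.53 (senescence) and +0.57 (DNA-damage
response) on its deposited dataset (GEO accession GSE90521). Those
numbers are *reproduction targets*, not shipped results: recomputing
them requires downloading the deposited CEL files, fRMA-normalising
them externally, collapsing probes with the platform annotation, and
running `stromaging run` on the result — and the original GSEA
variant (weighting, permutation scheme, sidedness) is not fully
documented, so both `weight_mode` settings should be tried and the
resolved configuration logged (the pipeline logs `fc_mode`,
`weight_mode`, scheme and seed for exactly this reason). On the
shipped 227-gene published DE list — a truncated universe in which
only the secretome set retains ≥ 3 members — the package computes a
negative secretome ES, matching the published direction.

## Known limitations

* The permutation p is bounded below by 1/(n_perm + 1); tiny sets give
  coarse p-values regardless of n_perm.
* No normalised enrichment score (NES) across set sizes and no
  leading-edge extraction; raw ES only.
* DE p-values are unadjusted by design; the DE call is a pure
  fold-change rule.
* The hypergeometric overlap test conditions on list sizes and assumes
  exchangeability within the common universe; cross-platform symbol
  harmonisation is the caller's responsibility.
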