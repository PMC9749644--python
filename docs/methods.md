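# Methods

## Model and procedure

`combimine` analyses a case–control genotype matrix (samples × SNPs,
ordinal coding 0/1/2, missing allowed) for high-order combinatorial
associations. The unit of analysis is the *feature state* — a SNP fixed at
one specific genotype — and the object of inference is the *disease
signature*: a set of 1–5 feature states on distinct SNPs whose joint
carriers (exact genotype match at every member SNP; a missing genotype
never matches) are over-represented among cases. All association
statistics reduce to the 2×2 carrier × case/control table: the
cross-product odds ratio (Haldane–Anscombe +0.5 applied only when a cell
is zero) and the two-sided Fisher exact p.

The pipeline runs in four stages — mining, permutation validation,
evaluation, annotation — followed by architecture clustering and
stratification. Each stage is an independent library function; the
`combimine` CLI orchestrates them with one global seed from which every
stage seed is derived via `SeedSequence(seed, spawn_key=(stage_index,))`.

### Mining

Two search modes over the feature-state space:

* **Exhaustive** enumerates every combination up to `max_order`
  level-wise, pruning branches whose case-carrier count falls below the
  prevalence floor (valid because carrier sets shrink monotonically as
  states are added). An evaluation budget (default 5×10⁷ combinations)
  refuses configurations that cannot finish.
* **Greedy-stochastic** starts from every singleton state passing the
  mining filters plus the strongest `n_random_starts` state *pairs*
  (screened by a pooled two-proportion z, then Fisher-scored), and extends
  each start by the feature states that strictly improve the score
  (−log₁₀ Fisher p), following the top `beam_width` (default 2) improving
  extensions per step. Every combination visited along a path that passes
  the filters is reported, so the result covers all orders, not just path
  termini. Pair starts exist because a true signature's member pair can
  have a *worse* Fisher p than one of its marginal singletons — a score
  valley that single-path hill climbing cannot cross. With `beam_width=1`
  and no pair starts the search reduces to plain greedy extension.

Within extension steps, candidates are ranked by the cheap z screen and
only the leading `max(8·beam_width, 32)` are Fisher-scored exactly; this
is a deterministic heuristic and is applied identically to observed and
permuted data, so the observed-versus-null comparison below stays
symmetric. The Fisher kernel itself is a vectorised hypergeometric
enumeration over a cached log-factorial table, unit-tested to 1e-12
against `scipy.stats.fisher_exact` and a from-scratch enumeration oracle.

Only case-enriched combinations (OR > 1) are reported by default;
protective mining is available behind a flag. Mining retains combinations
with `p < p_max` (default 0.05), case prevalence ≥ 5% and OR > 1, sorted
by (p, −OR, order, states).

**Choosing `p_max`.** The BH step in validation operates on permutation
empirical p-values whose resolution is 1/(n_perm+1). If mining emits m
nominal signatures of which k are real, validation can only succeed when
`1/(n_perm+1) ≤ α·k/m`; with a permissive `p_max` on a desk-scale panel, m
runs into the hundreds and the permutation budget must grow
proportionally. Analyses that can afford only tens of permutations should
tighten `p_max` toward the Bonferroni level of the number of combinations
searched (the demo config and the exhaustive-mode tests do this).

### Permutation validation

Labels are permuted uniformly (case:control counts preserved exactly;
deterministic per (seed, iteration)), and mining re-runs with identical
parameters on each permutation. A signature scores a *hit* in a
permutation iff the permuted result set contains a combination **of the
same order** with odds ratio ≥ the signature's observed OR **and**
case-carrier count ≥ its observed count. The hit count over `n_perm`
permutations is the permutation score (P1000 at n_perm=1000); empirical
p = (hits+1)/(n_perm+1), BH-corrected at FDR 0.05; survivors must also
meet the prevalence floor. Signatures with hit fraction below 5% are
additionally flagged as permutation-significant.

Order-stratified matching is a deliberate design choice. The permutation
null of a directed search is the distribution of *search maxima*, and
those maxima grow with combinatorial order: at 500 cases over 200 SNPs a
greedy order-5 null maximum routinely reaches OR 4–7 at 25–60 case
carriers, which would register a "hit" against any genuine order-3
signature and drive every signature's score toward n_perm. Comparing each
signature against the permutation stratum searched at the same
multiplicity restores the score's meaning; the order-agnostic variant
remains available (`hit_match="any_order"`). For efficiency, exhaustive
re-mining screens out combinations that are weaker on both axes than the
weakest signature under test — such combinations can never register a hit
— and computes exact p-values only for the survivors.

### Evaluation, architecture, annotation, stratification

Critical SNPs are those appearing in ≥ 2 validated signatures
(configurable). They are scored by a Random Forest (500 trees,
sqrt-features, unlimited depth) on raw ordinal genotypes with missing kept
as its own value, under stratified 5-fold CV; `rf_score` is the mean Gini
importance across folds, `cv_accuracy` the pooled out-of-fold accuracy.
Gene priorities are cumulative sums of critical-SNP scores; a SNP mapped
to several genes contributes its full score to each.

The architecture graph has one node per feature state of a validated
signature; states co-occurring in a signature are connected (every
signature induces a clique), weighted by the Jaccard similarity of the two
states' case sets (union of case carriers over the validated signatures
containing each state). Communities come from seeded Louvain modularity
maximisation at resolution 1.0 (connected components as an alternative),
relabelled canonically by descending pooled case count so node insertion
order cannot change output. A sample carries a community iff it carries
≥ 1 member signature; community OR/p come from the resulting 2×2 table.
Pairwise community overlap uses the smaller community as denominator
(Jaccard available via option).

Annotation is a positional cascade on 1-based closed coordinates: SNPs
inside a coding interval are assigned to that gene (class `coding`,
distance 0); remaining SNPs are assigned to the closest gene(s) whose
strand-aware window — gene body minus 2 kb upstream to plus 0.5 kb
downstream, boundaries inclusive — contains them; ties report all tied
genes. Windows anchor on the gene body by default (`anchor="tss"`
optional); BED input is converted from 0-based half-open at the boundary.

Stratification compares a community's case set against the remaining
cases: pooled two-proportion z for categorical covariates, Mann–Whitney U
(exact for tie-free samples of ≤ 8 per group, tie-corrected normal
otherwise, min-U convention) for continuous ones, BH across the features
tested per subgroup, missing values excluded pairwise. Forest-plot data
use percentile bootstrap CIs (default 1000 iterations). The GWAS baseline
is the allelic chi-square on 2N allele counts (Fisher optional) at
genome-wide α = 5×10⁻⁸. Replication restricts mining in a disjoint cohort
to combinations of a reference SNP set and reports reference SNPs
appearing in ≥ 1 validated signature.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: a
case–control cohort (default 2382 cases, 2:1 matched controls) of
independent biallelic SNPs in Hardy–Weinberg proportions with MAF drawn
uniformly from 0.05–0.5, no LD by default (a haplotype-copying block-LD
option exists but is off, since reported disease SNPs showed no LD), and
planted 3–5-SNP genotype-state signatures.

Disease status follows a liability model: log-odds(case) = baseline +
Σ β_s·I(carrier of signature s), baseline −3.0 (≈ 4.7% population risk).
For each signature, β_s and the population carrier probability q_s are
solved jointly by cyclic 1-D root finding (brentq, tolerance 1e-6 on the
OR scale) against closed-form expressions for the expected carrier
fractions among *sampled* cases and controls, enumerating the 2^K joint
carrier configurations exactly; member-SNP allele frequencies then realise
q_s^(1/k) per SNP under HWE, with an explicit infeasibility error naming
the signature when a target combination of OR, prevalence and genotype
states is unreachable (e.g. heterozygote probabilities above 0.5).
Sampling is retrospective: carrier configurations are drawn from their
exact label-conditional distributions, carriers receive the member
genotypes verbatim, non-carriers draw member genotypes from HWE
conditioned on not matching (rejection sampling). Under this model the
expected sampled OR equals the target exactly; the *realized* OR of one
cohort still fluctuates (multiplicative sd ≈ 1.25 at 50 case carriers),
which matters for the acceptance analysis below.

A separate *marginal-free* mode plants pure interactions for the
GWAS-contrast experiments: the penetrance of one exact multi-SNP genotype
cell is elevated and all other cells are adjusted by a constrained
least-squares projection so that every member SNP's per-genotype case rate
is flat — no single-locus allele-frequency difference in expectation, with
the target cell's sampled OR and case prevalence solved by nested root
finding. The projection is probability-weighted (deviations concentrate in
rare genotype cells, keeping non-target cells statistically quiet), and a
`purity="pairwise"` option additionally flattens every two-SNP joint case
rate, yielding an XOR-style interaction invisible below its own order.
Flatness constraints bound the achievable effect — a pairwise-flat 3-way
interaction caps near OR 3.3 at 12% case prevalence under the default
baseline — and the solver raises an explicit infeasibility error rather
than silently undershooting a target. Compensation mass is conserved, so
some non-target cells of the same SNP trio remain genuinely (if weakly)
case-enriched; with enough samples these side cells pass any fixed mining
threshold. This is why the architecture-recovery study scores community
recovery against the generator's truth labels (planted families in
distinct communities, planted case sets below the 20% overlap contract)
rather than demanding that the *recovered* communities' case coverage stay
narrow: genuinely associated shadows of a planted signal — sub-pair
combinations, their chance extensions, compensation side cells — survive
validation honestly and broaden recovered case sets at desk scale.
Covariates (binary via logistic shifts, continuous via mean shifts in SD
units) are applied to carriers per signature; a synthetic gene model
places each planted SNP inside a coding region, 1.5 kb upstream, or 0.4 kb
downstream of a named synthetic gene (cycling the three classes) for
annotation tests; a truth file records realized carrier sets exactly
recomputable from the emitted matrix.

What the generator does **not** emulate: linkage disequilibrium structure
by default, ancestry admixture, genotyping batch effects, imputation
uncertainty, sex chromosomes, and realistic covariate correlation
structure. Passing tests therefore demonstrate the pipeline's behaviour
under its own stated model, not performance on real array data.

## Problem sizes and numerical choices

The test and acceptance analyses run at desk scale, chosen so the full
suite completes in minutes on one CPU: cohorts of 500–1000 cases with 2:1
controls, panels of 20–200 SNPs, 25–200 permutations, 20 seeds for any
frequency claim. At these sizes the separation between a planted OR-3.7
signature and the null search maximum is only moderate: over 200
permutations the strongest same-order null combination at ≥ 50 case
carriers reaches OR ≈ 3.3–4.2. The permutation-score analysis of a
"strongly associated" signature is therefore stated — and implemented — as
conditional on the realized signature meeting its strength premise
(observed OR ≥ 3.5, prevalence ≥ 0.10); cohort draws whose sampled
realization falls below the premise are redrawn from the seed stream.

Other numerical choices: empirical p-values use the +1 correction so BH is
well defined; two-sided tests throughout; Fisher tie tolerance 1+1e-7 on
the pmf (matching scipy); exact SNP-HWE p by enumeration at fixed allele
counts; QC order fixed as samples → SNP missingness → MAF → HWE (exact
test in controls at 1e-6), autosomes first; QC thresholds (MAF 0.01,
missingness 0.05) are field-standard defaults, all configurable; control
matching samples without replacement within strata of the categorical
matching keys, seeded. Ancestry is a categorical label throughout (no
PCA).

## Known limitations

* The stochastic search is a documented stand-in for a proprietary
  large-scale platform; its sampling of the combination space differs, and
  at scale the permutation score depends on search capacity (held
  symmetric here between observed and permuted runs).
* Validation power is bounded by the n_perm/m interaction described above;
  desk-scale analyses must co-tune `p_max` and `n_perm`.
* The liability and marginal-free generators are stand-ins for unknown
  real genotype-generating mechanisms; cohorts mixing both signature types
  are not supported.
* Multi-allelic variants must be split before loading; phasing,
  imputation, relatedness pruning and covariate-adjusted (logistic) GWAS
  are out of scope.
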