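# Methods

This note records the model, the numerical conventions, and the design
choices behind `orphanfit`, including what the synthetic fixtures do and do
not establish about real data.

## Data model and normalization

A screen is a matrix of fitness scores, elements × conditions
(`ProfileMatrix`). Missing measurements stay missing; nothing is imputed.
Z-normalization is per condition over the finite entries of that column,
with the **population** standard deviation (divide by N): the set being
standardized is the full considered population of elements for that
condition, not a sample from a larger one. A column with fewer than two
finite values, or zero spread, is an error rather than silently dropped.
Z-normalization is idempotent to 1e-9 and preserves missingness.

Genomic coordinates are 0-based, half-open; an insertion at position *p*
belongs to region [start, end) iff start ≤ p < end. Insertions on both
strands are pooled. The fitness of a non-coding region in a condition is
the plain arithmetic mean of the raw per-insertion scores inside it; when
coding and non-coding regions are compared, both use this same averaging so
the comparison is not biased by the screen's gene-level reweighting.

## GPR collapse (reaction vectors)

GPR rules are parsed into disjunctive normal form (OR over isozyme clauses,
AND within a clause), distributing AND over OR for nested rules; duplicate
clauses collapse. The reaction score per condition is max over clauses of
(min over clause genes). Missing data policy: a clause containing an
unmeasured gene is not evaluable and is dropped; a reaction with no
evaluable clause is missing for that condition. The alternative — imputing
unmeasured genes as 0 — would bias the min/max toward 0, so it is not done;
instead the fraction of GPR genes with data is reported as coverage.

Order of normalization: for **fitness**, the raw gene scores feed the
collapse and only the reaction matrix is Z-normalized (the gene-level ZFV
used for candidate vectors is normalized separately). For **expression**,
gene values are Z-normalized per sample first, then collapsed, then the
reaction rows are re-normalized; expression datasets are processed and kept
separately (the per-dataset scores are averaged at the ALS stage — on the
fixtures this beats concatenating sample axes, which mixes incomparable
scales, and the averaging convention is pinned by a regression test).

## Neighborhood graph and pruning

Reactions are adjacent when they share at least one retained species;
species in different compartments are distinct, and stoichiometric signs
and magnitudes are ignored (presence only). Species frequencies are counted
once on the unpruned model. Candidates for removal are species with
frequency strictly above the cutoff (default 11), visited in descending
frequency, ties broken by species id for reproducibility. A tentative
removal is committed only if no reaction that currently has ≥ 2 non-orphan
profiled neighbors would drop below 2 — the constraint is checked globally,
not just at the focal reaction. Frequencies are not recomputed after
removals (removing a species does not change other species' membership
counts). Boundary/exchange reactions are not treated specially.

## Scoring and validation

Spearman correlations use average ranks for ties and pairwise-complete
observations with a minimum overlap of 3 conditions; a neighbor with less
overlap is skipped, and a reaction needs two usable neighbors to be scored.
The ALS is the mean of the two largest neighbor correlations. Candidate
ranking is descending by score with lexicographic tie-breaks on gene id, so
orderings are reproducible across platforms. The candidate pool is every
gene with a fitness vector.

Promoter adjustment adds α (default 0.21) times the sum of the candidate's
promoter ALS values; a gene without promoter annotation is unadjusted. The
combined score is the equal-weight average of the (promoter-adjusted)
fitness ALS and the expression ALS; if one source is unavailable for a
candidate the other passes through and the result is flagged
(`fitness_only`) rather than dropped.

Leave-one-out validation casts each adequate non-orphan reaction as an
orphan. Hiding a reaction removes its row from the reaction matrix
entirely — an orphan has no computable vector — so the per-condition
normalization of the neighbor vectors is recomputed without it, and the
reaction cannot serve as its own neighbor. Its true genes remain
candidates. `second_gene` mode restricts to reactions with ≥ 2 measured
genes, removes the best-ranked true gene, and records the rank of the next
(accounting for the one-position shift). Accuracy at k is the fraction of
reactions whose best true gene ranks ≤ k; it is non-decreasing in k by
construction.

Confidences compare an observed score σ to empirical distributions of
known-pair and spurious-pair scores from the LOO pass, with inclusive
survival fractions P(ALS ≥ σ). The Bayesian variant multiplies by the prior
probability of a correct pairing — computed from the loaded data as
(# true gene–reaction pairs)/(# genes × # non-orphan reactions), and
overridable — with the marginal formed as the prior mixture of the two
tails. The unbiased variant is the odds of the true tail against the sum of
both tails. A σ above every observation in both distributions has undefined
confidence (NaN), not 0 or 1. At genome scale the spurious-pair set is
capped by a seeded subsample (default 100 000 scores).

## Region-effect and ranked-list statistics

The region-effect test computes, per condition, a location statistic (mean,
10th/25th percentile, or median) per region class and counts the conditions
in which the focal class is strictly most negative; the p-value is the
exact inclusive binomial upper tail with null success probability equal to
the exact rational 1/(number of classes) — e.g. 1/7 for seven promoter
sigma classes, not the rounded 0.143, which changes the tail by several
percent at these magnitudes. Conditions missing a class are skipped and
reported.

Wilcoxon rank-sum class enrichment is one-tailed (class high); the exact
permutation distribution is used for n₁+n₂ ≤ 10 without ties, the
tie-corrected normal approximation otherwise. Callers remove class pairs
from the background and same-operon pairs from non-operon classes before
testing. Survival-ratio curves report log10 of the class-to-background
fractions of pairs at or above each threshold, with zero fractions flagged
undefined instead of mapped to ±∞. Gene-pair distance classes use
start-to-start distance on the same replicon with cumulative bin sizes
(5–100 kb); the GC filter removes pairs whose genes fall in the same
empirical GC-content decile (right-closed quantile bins).

The mHG statistic scans every prefix of a ranked 0/1 list and takes the
minimum inclusive hypergeometric upper tail; all-zero lists score 1 by
convention, and the minimizing prefix is the first one within 1e-12 of the
minimum (exact ties are common and float noise must not reorder them). The
mutual variant thresholds list a at every B, labels list b's ordering, and
minimizes over B; its empirical p-value is the fraction of 100 seeded
shuffles of list a scoring at or below the observed value. The mHG score is
a test statistic, not a p-value; only the shuffle p is calibrated. PSSM
scanning uses log₂-odds against a uniform background, both strands, max
over positions; the hit threshold is a caller-supplied configuration value.

## Synthetic fixtures: what they emulate

The generator builds linear 3-reaction pathways (end–middle–end) joined by
shared intermediates, so exactly the pathway middles have two neighbors and
are adequate; orphans are planted on middles. A currency species is placed
in 12 middles (capped at the number of middles for small models) so the
pruning step has a genuine >11-frequency removal candidate whose removal is
harmless. GPR rules are single-gene by default with 10% OR-pairs and 10%
AND-pairs, assigned to pathway ends first; gene ids are shuffled so roles
are not correlated with lexicographic order.

Latent condition profiles per pathway place the two end latents
symmetrically around the middle latent at correlation s (the
`signal_strength`) with end–end correlation max(2s² − 1, −s): for s ≥ ½
this is the smallest end–end correlation any valid covariance allows, which
makes the planted middle gene the *strongest* correlate of its reaction's
neighborhood with margin s − s² — maximal at the default s = 0.5. This is a
deliberate identifiability construction: under, e.g., exponential-decay
correlations along the pathway, the gene of a neighboring reaction always
outscores the true gene ((1+s²)/2 > s), and no method of this family could
place the planted gene first. Each pathway draws its own
empirically-orthonormalized basis, so within-pathway sample correlations
are exact (the noise-free recovery test is then deterministic up to rank
noise) while cross-pathway correlations are independent O(1/√n) noise. At
s = 0 no structure is planted at all — every reaction's latent is an
independent normal vector — so the planted gene is exchangeable with decoy
genes, giving a proper null for baseline-calibration checks. True genes
observe their reaction's latent plus N(0, noise_sd²) with noise_sd = 0.3 by
default (enough to make condition count matter without drowning the
margin); insertions inherit their gene's scores plus the same noise;
expression datasets carry the same pathway geometry with independent
realisations (optionally reusing the fitness latents verbatim when the
sample counts match).

What passing tests on these fixtures do **not** show: real metabolic
networks are not disjoint 3-step pathways, real fitness noise is neither
Gaussian nor homoscedastic, real GPRs reach 17 genes, and real screens
measure a biased subset of genes. The fixtures establish that the
implementation is correct and that the scoring is calibrated at its null —
not that any particular accuracy transfers to a real organism.

Two small-sample effects of the method itself are visible at toy scale and
documented here because they would otherwise look like bugs: (i) a gene
whose reaction defines one of the orphan's neighbors correlates perfectly
with that neighbor and therefore competes strongly (this is intrinsic to
neighborhood scoring, and negligible only when the candidate pool is
large); (ii) per-condition normalization couples every profiled gene to the
reaction-matrix column means by −1/R, so in leave-one-out the hidden
reaction's gene — whose row is removed — enjoys a ≈ +0.02 advantage in
top-20 hit rate at R = 60 relative to the uniform null. Both vanish at
genome scale (R ≈ 1500, thousands of candidates).

## Problem sizes

The default test and acceptance runs use the 60-reaction / 80-gene /
48-condition fixture: leave-one-out over its 14–20 adequate reactions takes
well under a second, 50-seed null calibrations ≈ 15 s, and the full
acceptance script ≈ 35 s on one CPU. These sizes were chosen as the
smallest at which every structural feature (pruning candidate above the
cutoff, two expression set sizes, orphans with two profiled neighbors) is
present.
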