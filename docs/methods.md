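# Methods

## Model overview

The package identifies candidate biomarker miRNAs from the structure of a
condition-specific lncRNA–miRNA–mRNA (ceRNA) network. The working
assumptions are: (i) miRNA–target regulation is adequately represented as
two binary bipartite networks (miRNA–mRNA, miRNA–lncRNA) pooled from
evidence sources; (ii) a lncRNA and an mRNA act as competing endogenous
RNAs when they share significantly many miRNA regulators; (iii) the
regulatory edges that matter for biomarker status are *single-line* —
a target whose only regulator in the network is one miRNA — because they
are unbuffered; and (iv) condition relevance is conferred by differential
expression of the miRNA and mRNA ends of a triplet.

## Triplet inference

For each (lncRNA, mRNA) pair sharing ≥ 1 miRNA, the overlap k of their
regulator sets (sizes K and n) is tested against the hypergeometric
upper tail with universe N, computed exactly via `scipy.stats.hypergeom`.
Choices a user should know:

* **Universe N** (`universe`): the union of the miRNA node sets of the two
  source networks by default. The union is the natural population both
  regulator sets are drawn from; `intersection` and a fixed integer are
  offered for sensitivity analysis because the choice shifts every
  p-value monotonically (larger N → smaller tails).
* **Test family**: only pairs with k ≥ 1 enter the BH family. k = 0 pairs
  cannot form triplets; including them would only dilute the FDR control.
* **Inheritance**: significance is a pair property; each of the pair's k
  shared miRNAs yields one triplet. Hence the identity
  |triplets| = Σ_significant pairs k, which the tests assert on every
  simulated instance.
* **Threshold**: adj.P < 0.01 (strict), configurable as `alpha_triplet`.
* No expression-correlation filtering of triplets: the construction is
  purely structural by design.

Pair results are sorted lexicographically so outputs are byte-stable.

## Differential expression

The DE stage is an interchangeable engine, not a contribution: `welch` is
scipy's unequal-variance t-test; `moderated` shrinks per-feature pooled
variances toward a prior estimated by method of moments on log variances
(trigamma inversion by Newton iteration), with posterior variance
(d0·s0² + d·s²)/(d0 + d) and d + d0 degrees of freedom. It is a standard
empirical-Bayes moderated t, not a replication of any specific package;
a precomputed DE table can be swapped in (`de_results_from_table`).
Conventions: log2FC = case mean − reference mean (so biomarkers
down-regulated in the case group have negative values); DE requires
adj.P < 0.05 **and** |log2FC| > 1, both strict; a feature constant in both
groups gets p = 1 by convention and is flagged `degenerate`.

## Condition-specific extraction and NSR

Extraction keeps triplets whose miRNA **and** mRNA are DE (either
direction); lncRNAs are never filtered by expression — the surviving
lncRNAs are the inferred functional lncRNAs. NSR is computed on the
*extracted* network's projections, not on the global reference: the
projection deduplicates edges (an edge is a regulation, not a triplet
count), and a target is single-line to miRNA m when m is its only
projection partner. This is the operative definition throughout:
restriction changes degree-1 status, deliberately.

## Significance of NSR values

The per-miRNA test pairs miRNA m's count against every other profiled
miRNA's count and applies a one-sided Wilcoxon signed-rank test to the
differences (alternative: median difference > 0), dropping zero
differences. Because the differences routinely tie in absolute value,
the exact null is enumerated by dynamic programming over doubled midranks
(exact up to 25 nonzero differences, then a tie-corrected normal
approximation without continuity correction). scipy's `wilcoxon` is used
as a cross-check oracle in the tests where |d| are untied, since its
exact path does not admit ties. The `empirical` alternative,
p = (1 + #{j ≠ m : NSR_j ≥ NSR_m}) / n_miRNAs, gives the same ordering
and is floored at 1/n, so with few profiled miRNAs it is strictly more
conservative at a fixed alpha.

A candidate must have all three metrics significant at alpha = 0.05 (raw
p; no multiplicity correction across metrics or miRNAs — the selection
rule is a stated filter, not an inference). Profiles with fewer than
three miRNAs cannot be tested; the model then calls no candidates and
warns. Output ordering: nsr_sponge descending, ties by miRNA ID.

## ROC evaluation

AUC is the Mann–Whitney concordance probability with ties counted ½,
computed from midranks. Orientation `auto` reports max(a, 1 − a) with the
implied direction, so discriminative ability is direction-symmetric and
all reported AUCs lie in [0.5, 1]; `fixed` orients by the sign of the
feature's log2FC instead.

## Synthetic data: what it emulates and what it does not

The generator builds the structure the model assumes, at a scale a
single CPU handles comfortably (the defaults below define the study
conditions used by the tests):

* 50 miRNAs, 400 mRNAs, 200 lncRNAs; Erdős–Rényi background edges at
  density 0.01 per bipartite side (a configuration-model degree sequence
  is deliberately not the default; ER is analyzable).
* 5 planted biomarker miRNAs, each with 8 exclusive mRNA and 8 exclusive
  lncRNA partners. Each partner is co-targeted by a shared pool of 10
  *support* miRNAs that are never DE. The co-targeting is what makes the
  partner pairs hypergeometrically significant (k = 11 shared miRNAs out
  of a 50-miRNA universe); after DE extraction the support miRNAs drop
  out and each partner is single-line to its planted miRNA. A partner
  that were degree-1 in the *source* network could never pass the
  overlap test (k = 1 gives P ≥ 1/N = 0.02 > 0.01), so single-line
  structure must be planted at the condition-specific level — which is
  also where the model measures it.
* 15 decoy DE miRNAs sharing a co-regulated block of 6 DE mRNAs and 6
  lncRNAs: they populate the condition-specific network with zero
  single-line power, providing the background the signed-rank test needs.
* Expression: Gaussian log2 values (baseline 7.0, sd 0.5), 15 samples per
  group; planted and decoy miRNAs, planted partner mRNAs and block mRNAs
  shifted **down** by 2.0 in the case group.

Collisions — background edges touching a planted partner — are reported
per partner with a flag for whether the extra regulator is itself DE
(only those can break single-line status downstream). At density 0 the
recovery is exact: every planted miRNA scores exactly its planted counts.

What the generator does **not** emulate: heavy-tailed degree
distributions of real miRNA-target data (available via higher densities
or custom edge lists, not the default), array-specific noise or
normalization artifacts, correlated expression between interacting
features, and annotation noise in identifiers. Passing recovery tests
therefore demonstrates correctness of the machinery under the stated
generative assumptions, not performance on real interactomes.

## Numerical choices and degenerate inputs

* Exact hypergeometric tails (no approximations) at all tested sizes.
* BH via `statsmodels.multipletests(fdr_bh)`; p-values validated in (0, 1].
* Signed-rank DP uses float probabilities over ≤ 2·n(n+1)/2 + 1 support
  points; error is at machine precision for n ≤ 25.
* Welch p-values are clipped into (0, 1]; zero-variance features handled
  by convention (see above).
* Empty networks: `restrict` and extraction may legitimately produce
  empty results (warning, not error); `compute_nsr` refuses an empty
  network; the model converts an empty extraction into an empty
  candidate list.
* Determinism: all randomness flows from explicit seeds; reports are
  sorted on primary keys so repeated runs are byte-identical.

## Test and acceptance problem sizes

Oracle suites use 200 random instances per primitive (networks ≤ 50
nodes, ROC inputs ≤ 18 samples) and exhaustive hypergeometric
enumeration up to N = 20 (literal draw enumeration up to N = 8);
pipeline recovery and null calibration each average 20 seeds of the
default configuration. These sizes were chosen to make every check
exact or tightly calibrated while keeping the full suite fast.

## Known limitations

* The Wilcoxon pairing (each miRNA against all others) is one defensible
  reading of "per-miRNA signed-rank significance"; published per-count
  p-values from other studies are not reconstructable without knowing
  their background set, so only orderings and definitional identities
  are compared against published tables.
* Only lncRNAs and mRNAs are modelled as competitors; circRNAs and
  pseudogenes are out of scope.
* The moderated-t engine approximates, but does not replicate, limma;
  for publication-grade DE on real arrays, fit limma externally and feed
  the table in.
* No GO/KEGG/pathway enrichment (external services) and no plotting of
  publication figures beyond the quick-look NSR bar chart.
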