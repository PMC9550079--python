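# Methods

This note documents the models and procedures implemented in `barconcord`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make the
results reproducible.

## Distances

All comparisons use the uncorrected p-distance under **pairwise deletion**:
a site enters a pairwise comparison only when both sequences carry A, C, G
or T there; gaps, `?`, N and all other IUPAC ambiguity codes are excluded
per pair. Pairs sharing fewer than `min_overlap` sites (default 100) are
*undefined* (NaN) rather than noisily estimated; the raw per-pair overlap
counts are kept in the matrix so stricter rules (the 300-site best-match
fallback) can re-mask without recomputation. Whether to use pairwise or
complete deletion was an open design point; pairwise was chosen because the
pipeline routinely mixes full-length barcodes with shorter reference
fragments, where complete deletion would discard most of the alignment.
p-distances are treated strictly as dissimilarities: no code path assumes
the triangle inequality.

Before distance computation the alignment is trimmed so that the columns at
which *every* retained sequence is unambiguous number at least
`min_common = 150`. The removal rule is greedy: repeatedly drop the
sequence whose removal most enlarges the common core (ties broken by fewest
unambiguous sites, then id), stopping when the target is reached and
failing if even two sequences cannot share it. Greedy removal is not
globally optimal in general, but each step is locally optimal and the
procedure is deterministic.

## Barcode-gap partitioning

The recursive gap partitioner takes a prior intraspecific divergence P and
relative gap width X (default 1): sort the defined pairwise distances
ascending; scan for the first gap whose **upper edge exceeds P** and whose
width exceeds X times the local spacing scale, estimated as the mean
spacing over a trailing window of W = max(3, ⌈0.1·N⌉) sorted values; split
at the gap midpoint by linking all pairs below it (connected components);
recurse within each multi-member group until no significant gap remains.
Candidate gaps are keyed on the upper edge because the prior is a ceiling
on *intra*specific divergence: the barcode gap of interest starts below P
and ends above it. Numerical fidelity to the original ABGD web service is
explicitly out of scope; the binding contract, enforced by tests, is the
**clean-gap property**: whenever the realized maximum intraspecific
distance a is smaller than the minimum interspecific distance b, every
prior in [a, b) returns exactly the true partition.

Two behaviors of the prior sweep (20 log-spaced priors over
[10⁻⁴, 10⁻¹]) deserve note. Priors inside the barcode gap form a plateau
at the true species count. Priors *below* the intraspecific scale
deliberately oversplit — with finite sequences the pairwise distances live
on a lattice of multiples of 1/overlap, and at tiny priors the first
significant gap sits at haplotype scale. This oversplitting is a feature,
not a failure: the representative-selection step exploits it (see below),
and it is why the modal group count across the full sweep generally
*exceeds* the species count whenever within-species variation is non-zero.
Consumers who want "the" species count should read the plateau, not the
mode; the reported groups-versus-prior curve makes the plateau visible.

Representative selection for tree building runs the partitioner at the
oversplitting prior P = 10⁻⁴, samples up to k = 3 members per group with a
seeded generator (groups are visited and sampled in sorted order, so output
is a pure function of the seed), and collapses exact duplicate residue
strings to unique haplotypes.

## Single linkage and best-match fallback

The BIN-proxy clusters sequences by single linkage at threshold 0.022
(connected components of the d ≤ 0.022 graph; undefined pairs contribute no
edge). The true refined-single-linkage algorithm behind BINs runs only
inside BOLD's infrastructure; genuine BIN assignments enter the pipeline as
imported partitions instead. The fallback rule for sequences outside a
partition's scope follows barcoding practice: adopt the best match's group
when at least 300 sites are shared and similarity (1 − d) is at least 0.99;
equally distant best matches in different groups leave the query
unassigned — reproducibility beats an arbitrary choice.

## Single-threshold mixed Yule-coalescent

Given a rooted ultrametric genealogy (root-to-tip depths equal within
relative tolerance 10⁻⁶; ≥3 tips), each candidate threshold T — the
midpoints between successive distinct node heights, plus one below all of
them — cuts the tree into clusters: the maximal subtrees whose stem branch
crosses T, with tips whose pendant branch crosses T as singletons.

The likelihood walks the branching events from the tips toward the root.
Within each inter-event interval k of duration x_k the total rate is

    b_k = λ_b · n_k^{p_b} + λ_w · Σ_j n_{j,k} (n_{j,k} − 1)^{p_w}

with n_k the between-species lineages (branches deeper than T, cluster
stems below T, singleton tips) and n_{j,k} the within-cluster lineages of
cluster j. An interval ending in a branching event contributes
log b_k − b_k x_k; the tips-to-first-event interval is included; T is
inserted as an extra breakpoint so the rate classes are piecewise constant;
simultaneously tied events each contribute a log-rate term computed from
the tip-ward lineage counts. Counting lineages on the tip-ward side of
each event means a cluster's first coalescence sees n(n−1) ≥ 2, never a
zero rate. Exponents default to p_b = p_w = 1 with an option to optimize
them; the two rates are maximized per threshold by L-BFGS-B on log-rates
(the objective is concave in the rates). The null model is a single
process λ·n over all events, whose MLE is closed-form. Because the
below-all-events candidate reduces the mixed model to that null exactly,
logL_model ≥ logL_null holds by construction. Significance uses a χ² test
with 3 degrees of freedom, the conventional choice for this model family;
on pure-birth trees with no species structure it rejects at ≈1–3% at the
5% level, i.e. conservatively.

One boundary case: for a tree whose tips all coalesce near the present,
"everything is one species" is not representable (the threshold is
constrained to (0, tree height)); such trees instead come out with a
non-significant test, which is the operationally equivalent verdict.

## Reference matching, novelty and provisional names

Matching is exhaustive against the local reference library (records tagged
EXTERNAL): per study sequence, all references with similarity ≥0.80 are
ranked by distance then id, truncated to 100, and classified by exact
comparison of whitespace-normalized names (no synonym resolution — that is
taxonomy, not computation); provisionally named references are excluded by
default. A morphospecies is *divergent-novel* when the minimum best-match
distance over all its study sequences exceeds 0.05, with empty match lists
counting as exceeding — the minimum (not per-sequence) rule means one good
match anywhere clears the morphospecies. *First-barcode* flags are exact
name-absence checks restricted to non-provisional morphospecies.

The provisional flag itself is explicit metadata, never inferred from label
text ("sp.", "cf."): open nomenclature records an expert's judgment, and a
helper may only *suggest* the flag. Provisional resolution inspects, per
method, which described-name labels share a putative species with the
provisional morphospecies over the merged scope: all methods empty →
SEPARATE; all methods agree on the same non-empty name set → GROUPED_WITH;
anything else → MIXED with per-method detail. The nearest-reference note
reports the best library match below 0.05, else NO_MATCH.

## Discordance classification

For every study morphospecies the partitions are interrogated in two
scopes: restricted to study specimens (context H) and over the merged
study + external scope (context A). H strictly dominates: an issue already
visible within the study data is tagged H even when also visible merged.
A method that covers none of a morphospecies' specimens is *not evaluable*
and is excluded from the unanimity quantifier (absence of evidence). The
resolution flag R is set exactly when the triggering method set differs
from the evaluable set. Lumps are reported once per connected component of
the co-occurrence graph over morphospecies (an edge whenever two labels
share a putative species under any method), not once per pair, so a chain
of co-lumped names produces a single record listing all members. A
morphospecies can legitimately carry both a split and a lump record; one
that carries neither is concordant, and every morphospecies lands in
exactly one of those states.

## Synthetic data

The generator produces the statistical structure the analysis assumes —
tight clusters separated by a barcode gap — with full knowledge of the
truth. Species ancestors sit on a simulated pure-birth tree (the
simulator's zero-length youngest tip pair is extended by one further
exponential waiting time, as in the reconstructed Yule process). Node
heights are then affinely recalibrated so the shallowest species split
equals the sister-species target `inter_divergence` (default 0.10) and the
root equals `max_divergence` (default 0.25, about where COI p-distances
saturate in practice); without this the deepest splits come out absurdly
large and threshold-based delimitation rationally treats shallow
speciations as coalescence. Sequences evolve by an exact Jukes-Cantor
transition draw: along a branch of length b, each site changes with
probability ¾(1 − e^{−4b/3}) to a uniformly chosen other base, so realized
p-distances hit their targets in expectation (the JC inversion
d = −¾ ln(1 − 4p/3) converts target p-distances to branch lengths).
Individuals hang off their species tip as a binary near-star ladder of
coalescences staggered within 20% below the within-species depth, which
itself is jittered ±25% per species (species differ in diversity; this
also avoids exactly tied node heights). Default sampling is 8 species ×
4 individuals of 650 bp with 1% within-species divergence and 25% of
specimens serving as the reference library.

Scenario injections rewrite morphospecies labels only — the truth
partition is never touched — so every injected discordance is checkable:
`CrypticSplit` (one label, two species), `Lump` (two labels, one species),
`Misid` (random label swaps), `ProvisionalFraction`, `ShortFragment`
(flank masking). The generator does **not** emulate codon structure, rate
heterogeneity across sites, selection, recombination, saturation or
coalescent demography; passing tests therefore demonstrate correct
behavior on clean barcode-gap data, not robustness to gapless or
introgressed real-world datasets, where delimitation methods genuinely
disagree.

## Problem sizes and determinism

The test suite and the acceptance script run synthetic studies of 2–8
species with 3–6 individuals each (tens of sequences, hundreds of
distance pairs), 50-replicate recovery checks, and 100–200 pure-birth
trees of 20 tips for the null calibration — sizes at which every check
completes in seconds while leaving the asymptotics to the underlying
closed forms. All stochastic steps take explicit seeds (no global random
state); identical inputs and seeds yield byte-identical files, which the
pipeline manifest verifies by checksum.
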