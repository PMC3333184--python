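# Methods

## The prioritization problem and the data model

A gene network is an undirected graph over opaque gene-identifier
strings with edge weights ω ∈ (0, 1]. Two regimes are supported: an
unweighted protein-interaction-style network, where every ω is forced
to 1 and a gene's strength k_i equals its degree, and a weighted
functional-association-style network (e.g. STRING combined scores
rescaled from 0–1000 to (0, 1]), where k_i = Σ_v ω_iv. Disease
families map a family identifier to a set of causative genes; families
provide the seed sets for prioritization. A position table
(gene → chromosome, start) exists purely to define the linear gene
order needed by the simulated-linkage scenario; only relative order is
used.

Loading applies fixed hygiene rules: self-loops are dropped, duplicate
pairs in either orientation are collapsed, family members absent from
the network are removed first and families left with fewer than two
members are then removed. Duplicate-edge conflicts keep the **maximum**
weight — a deliberate choice (order-independent, preserves the
strongest evidence) where no canonical rule exists. An edge whose
rescaled weight is exactly 0 is dropped, since a zero-weight edge is
indistinguishable from no edge in every formula. One dialect
extension: a single-column line in an edge list declares an isolated
node, so networks containing unconnected genes round-trip through the
writer/reader with an identical node set.

## The ICN score

    ICN_ij = ω_ij + ( Σ_{u ∈ N_i ∩ N_j} ω_iu · ω_uj ) / E_ij ,
    E_ij = k_i · k_j / Σ_g k_g .

The direct term rewards an existing edge; the connector term rewards
shared interaction partners, normalized by the number of connectors a
pair with strengths (k_i, k_j) would be expected to have, so that hubs
do not accumulate credit merely by degree. When the connector sum is
zero the normalized term is defined as 0 (this also covers isolated
endpoints, where E_ij = 0 would otherwise divide by zero). The score
of a gene with itself is undefined and raises an error; no part of the
pipeline needs it.

The connector aggregation is pluggable (`formula=` on `icn_score` /
`candidate_scores`): `"product"` (default, above) multiplies the two
connector-edge weights, `"average"` takes their mean. The two coincide
on unweighted networks. The default is the product form because it
treats the two legs of a connector path symmetrically and vanishes
whenever either leg does; swapping in another aggregation is a
one-line change and the oracle tests are parametrized over formulas.

Candidate scoring sums ICN over the seed set
(Score_i = Σ_{j ∈ S_d} ICN_ij). A candidate that is itself a seed —
possible in the linkage scenario, whose windows are purely positional —
is scored against the *other* seeds. For the default formula the
computation is vectorized with sparse matrix products
(A[candidates] · A[:, seeds] yields every connector sum at once); the
pairwise path is retained for other formulas and as the shape of the
brute-force test oracle.

Ranks are assigned descending by score; tied scores share the average
of the ranks they span (two genes tied for positions 1–2 both get
1.5). Average ranks avoid order-of-input artifacts and feed the rank
product deterministically.

## Propagation baselines

Random walk with restart iterates p⁽ᵗ⁺¹⁾ = (1−r) W p⁽ᵗ⁾ + r p⁰ from
p⁽⁰⁾ = p⁰, with W column-stochastic (column v distributes ω_uv / k_v to
each neighbor u) and p⁰ uniform over the seed genes. Isolated nodes
get a self-transition of 1, keeping W stochastic so the iterate sums
to 1 at every step. PRINCE-style propagation iterates
F⁽ᵗ⁾ = α W′ F⁽ᵗ⁻¹⁾ + (1−α) Y from F⁽⁰⁾ = Y with the symmetric
normalization W′ = D^(−1/2) W D^(−1/2); its limit is
(1−α)(I − αW′)⁻¹Y. The prior Y is the plain binary seed indicator —
the full PRINCE algorithm weights the prior by phenotype similarity,
but no phenotype input is part of this pipeline, so the simplification
is deliberate and documented. Isolated nodes keep a zero W′ row; an
isolated seed's limiting score is therefore (1−α).

Both methods halt when the L1 change between successive vectors falls
below the tolerance (default 10⁻¹⁰) and record the residual sequence,
so tests can verify the halting rule fires exactly at the threshold.
Defaults r = 0.5 and α = 0.9 are the fixed, conventional settings for
these methods; a safety cap of 10⁶ iterations turns a non-converging
run into an explicit error carrying the last residual (with r > 0,
resp. α < 1, the iteration is a contraction and converges in practice
within tens to hundreds of steps).

## Rank-product combination

CS_i = Π_j R_ij over the contributing methods, re-ranked ascending
(lowest product = best). Fractional ranks from tie-averaging multiply
as-is; tied products again receive average final ranks. The
combination is invariant to the order in which method rankings are
supplied and requires identical candidate sets (mismatches raise,
listing the symmetric difference). Presets `icn-rw`, `icn-pr`,
`rw-pr`, `icn-rw-pr` name the standard pairings.

## Leave-one-out harness

One trial per (family, member) association: the member is held out,
the remaining family is the seed set, and every method is scored on
the identical candidate set. Scenario `linkage` takes the 100
network-present genes nearest the test gene on its chromosome (50 per
side where possible, borrowing from the other side at chromosome
ends) plus the test gene — 101 candidates. Restricting to
network-present genes keeps every candidate scoreable; unscoreable
padding would be auto-ranked last and flatter every method. A
chromosome with too few genes yields a smaller set plus a recorded
warning; an unpositioned test gene skips the trial with a reason.
Scenario `genome_scan` uses all network genes minus the other family
members. Success at cutoff k means rank ≤ k; with average-tie ranks a
gene tied across the boundary (rank k + 0.5) counts as a failure,
which is the conservative reading. A method failing to converge in a
trial records rank NaN and counts as unsuccessful. Trials whose
held-out gene is disconnected from every seed are kept — they are
legitimately hard cases, not artifacts.

The harness additionally reports: the Venn-style breakdown of top-1
successes by exact method subset plus the union; rescued cases (trials
failed at k = 1 by every single method but succeeded by a combination
preset); and, for genes found by exactly one method, their degree and
mean unweighted shortest-path hop distance to the other family
members (unreachable members are excluded from the mean and counted,
not set to infinity). Method-unique groups are compared per metric
with a two-sided Mann-Whitney rank-sum test — the appropriate unpaired
rank test for groups of unequal size; a paired signed-rank test is not
applicable to these groups. Comparisons involving an empty group are
skipped with a notice.

## Synthetic benchmark generator

A planted-partition graph: genes in the same module connect with
probability `p_within`, all other pairs with `p_between`; each module
is emitted as one disease family. Weight models: `unit` (unweighted),
`uniform(lo, hi)` and `beta(a, b)` for confidence-style weights in
(0, 1]. Edges are drawn before weights, so specs differing only in
weight model share a topology. Positions shuffle the genes with the
seeded generator, deal them round-robin across chromosomes and assign
strictly increasing starts — family members end up scattered, so a
linkage window around a disease gene holds mostly unrelated background
genes, as a real linkage interval would.

Profiles: `tiny` (2 modules × 5 genes, 50 background, p_within 0.9,
p_between 0.02) is sized for fast unit tests; `default` (8 × 15,
1500 background, p_within 0.3, p_between 0.005, unit weights) gives a
background gene an expected ~8 random partners and a module gene ~4
additional within-module partners — enough planted signal to separate
real module membership from noise without making recovery trivial;
`weighted` shares the default topology with beta(2, 2) weights. All
output is a pure function of the spec including its seed.

The generator emulates modular disease architecture and confidence
weighting. It does **not** emulate scale-free degree distributions,
ascertainment bias toward well-studied genes, correlated noise between
interaction databases, or genomic clustering of paralogous family
members. Passing the planted-module benchmark therefore demonstrates
that the implementations are correct and that the methods recover
modular signal; it does not predict their relative performance on real
interactome data.

## Numerical and design notes

- Node order is lexicographic everywhere; every matrix/vector view,
  tie-break and iteration order derives from it, making reruns
  byte-identical.
- Ranked lists are written with `%.17g` floats so TSV round trips are
  exact.
- The benchmark problem size (1620 genes, ~6.9k edges, 120
  associations) was chosen so a full two-scenario evaluation completes
  in seconds while each linkage chromosome still holds the full
  101-gene window.
- In the linkage scenario other family members can fall inside a
  positional window and legitimately outrank the held-out gene; this
  depresses top-1 rates for all methods, most visibly the propagation
  methods (a seed retains restart/prior mass by construction). It is a
  property of the scenario, not a bug.
- Known limitations: no all-pairs ICN materialization or approximation
  for genome-scale networks (each trial computes only what it needs);
  no phenotype-similarity input; no order-statistics or
  discounted-rating rank aggregation; no degree-heterogeneity knob in
  the generator.
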