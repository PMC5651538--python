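# Methods

This note documents the models and procedures implemented in `longinet`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions used where the design
was genuinely open.

## Aging-gene curation

Gene identity is the upper-cased symbol string; no alias resolution is
attempted, so lists using different nomenclatures for the same gene will
under-count overlaps. Non-human lists are mapped through a
(organism, source gene) → human symbol table; one-to-many mappings expand
to all human symbols, since collapsing them would discard evidence and
deduplication happens at the catalogue level anyway. The organism-support
filter counts only non-human organisms (CE, DM, MM, SC): the criterion is
cross-species replication of an aging phenotype, which human (HS)
evidence cannot contribute to by definition. The default support
threshold is 2 organisms. Pooling the cross-organism survivors with the
human list is a plain set union.

Overlap significance is a one-sided over-representation test:
P(X ≥ overlap) with X hypergeometric(N, |B|, |A|). One-sided is the only
direction consistent with testing *enrichment*; the statistic is
symmetric in the two sets. The default background universe is the
N = 20,462 protein-coding gene count; callers testing curated sets that
live in a smaller annotation space should pass their own universe, since
the p-value is sensitive to it. The odds ratio reported is the sample
odds ratio of the 2×2 table (infinite when a margin cell is empty).
Gene-set (GMT) enrichment applies the same tail per term with
Benjamini–Hochberg correction across terms.

## Activity filtering and network construction

The five record-level criteria are applied in a fixed order and the first
failure is logged, so rejection counts per criterion are reproducible.
The potency threshold (default 10 μM) is inclusive. Values are compared
in micromolar; the loader converts from an explicit units column
(pM/nM/μM/mM/M) and defaults to μM. Organism matching is an exact string
comparison after whitespace/case normalization — "Homo sapiens" matches
"homo  SAPIENS" but not strain-suffixed variants; this is a documented
limitation, not a fuzzy matcher.

Structure standardization keeps the largest carbon-containing fragment
(ties by heavy-atom count, then canonical-SMILES order), canonicalizes it
and derives the InChIKey, all through RDKit. Compounds are deduplicated
by InChIKey with first-seen-id precedence and aliases retained. When one
(drug, target) pair has several passing records the edge stores the most
potent value.

Networks are bipartite graphs with typed nodes; merging is edge-set
union, with provenance accumulating into a set, so an edge observed
experimentally and predicted computationally carries both labels and
merging is commutative. Sparsity is 100·edges/(drugs·targets). The
two-decimal reported form *truncates* rather than rounds, matching the
reporting convention of the reference network tables this statistic
reproduces (2,408/(224·494) = 2.176% prints as 2.17); the raw value is
retained alongside.

The degree-distribution comparison is a one-sided Mann–Whitney rank-sum
test. Small samples (≤ 8 per side) are handled by exact enumeration of
group-label assignments over midranks, reporting the inclusive tail
P(S ≥ s) when the pooled sample has no ties and the mid-p
(#{S > s} + ½#{S = s})/M when it does; larger samples use the
tie-corrected normal approximation with continuity correction, and a
fully degenerate null (zero variance) reports p = 0.5. Compound
clustering is deterministic k-medoids (greedy BUILD then SWAP) under
Tanimoto distance on substructure-key sets; two empty profiles are at
distance 0, an empty vs. non-empty profile at 1.

## Substructure-based target inference

The diffusion operates on the tripartite graph of drugs D, targets T and
substructure keys S, with D–T edges from known interactions and D–S
edges from fingerprint profiles. The default substructure dictionary is a
compact built-in set of ~50 SMARTS patterns (functional groups, ring
systems, halogens); it is a pluggable stand-in for large published
dictionaries such as Klekota–Roth, and any (key, SMARTS) table can be
substituted via the loader.

Parameters and their roles (defaults follow the published setting
α = β = 0.1, γ = −0.5, k = 2, top-20):

- **α** splits the query drug's unit initial resource between its two
  neighbor classes. The minority share α goes to substructure neighbors
  by default (`alpha_to="substructures"`); the literature leaves the
  direction ambiguous, so it is exposed as a switch.
- **β** splits each drug's outgoing mass between target edges (1 − β)
  and substructure edges (β), shared equally within a class; a drug with
  only one class sends it everything. Targets and substructures split
  their mass equally over drug neighbors.
- **γ** damps hubs: every transfer into node i is scaled by deg(i)^γ with
  no renormalization. At γ = 0 the transfer matrix is column-stochastic
  and total resource is conserved exactly (this limit is tested to
  1e-10); γ < 0 bleeds resource away from hubs, so totals shrink — this
  is intentional, not a defect.
- **k** is the number of diffusion steps. Even k is required: an odd step
  leaves resource on drug nodes where target ranking is meaningless, so
  odd values are rejected at parameter validation rather than silently
  projected.

Candidates are target nodes not already linked to the query drug, ranked
by final resource with ties broken by ascending target id; scores are
plain double precision with no small-score thresholding. The
implementation is validated against a dense matrix-power oracle on small
random networks (max |Δ| < 1e-9). The construction reproduces the stated
roles of the four parameters; no claim is made of bit-compatibility with
any specific prior implementation's matrix, whose normalization details
are not fully published.

## Permutation indication scoring

The null hypothesis is that a compound's targets fall on AAPs at the
genomic background rate. Each permutation draws K genes (K = the AAP set
size, 411 under the defaults) uniformly without replacement from the
N = 20,462-gene universe and records the overlap with the compound's n
fixed targets. The implementation samples this draw by the exact
sequential conditional scheme — target t is included with probability
(K − j)/(N − t) given j of the first t targets included — vectorized
across permutations; this is distributionally identical to materializing
the K-subset and intersecting, at O(n·n_perm) cost. The overlap is
exactly hypergeometric(N, K, n), and the closed-form moments
μ = nK/N, σ² = n(K/N)(1 − K/N)(N − n)/(N − 1) with the summed tail serve
as the independent oracle in the tests.

Conventions:

- The nominal P counts permutations with S ≥ x (`at_least`), the standard
  permutation convention; the strict S > x reading is available as
  `tail_mode="strict_greater"` but makes P < 1 for x = 0, which misorders
  degenerate compounds.
- No pseudocount by default, so P can be exactly 0 at 100,000
  permutations; a (hits+1)/(m+1) switch exists for users who need
  never-zero p-values.
- σ̂ uses the sample (m − 1) denominator; Z is undefined (NaN, not ±∞)
  when σ̂ = 0. K defaults to the size of the supplied AAP set.
- Each drug scores on its own RNG substream derived from (seed,
  SHA-256(drug id)), so results are independent of iteration order and
  stable under cohort subsetting.
- BH q-values are computed across all scored drugs in the run; the final
  table ranks by ascending q, then descending Z, then drug id.

A consequence worth knowing: the overlap statistic is integer-valued and
coarsely discrete at realistic target-set sizes, so permutation p-values
are super-uniform. For n = 6, K = 411, N = 20,462 the achievable levels
near the 5% mark are 0.115 and 0.0057 — nothing falls in between — so
the fraction of null compounds with P ≤ 0.05 is far *below* 0.05 (about
0.007 at the generator's default degree mix). The test is conservative:
type-I error is controlled but not exhausted, and no choice of (n, K, N)
in this problem's range makes the rejection rate sit at the nominal
level.

## Synthetic data

The generator emulates the shapes of the real study inputs with known
ground truth: a 20,462-symbol gene universe with a 411-gene AAP subset;
per-organism curation inputs sized so that 1,006 genes appear in ≥ 1
non-human organism, 130 in ≥ 2 (12 in ≥ 3), sharing 28 genes with a
309-gene human list and pooling to exactly the 411-gene AAP subset;
activity-record mixes violating each filter criterion once per configured
repeat plus an inclusive-boundary record at exactly 10 μM; and drug–target
networks with truncated power-law drug degrees (exponent 2.2, range 3–30
by default, echoing hub compounds with degree ≈ 70 alongside a small
median) over 400 targets of which 8 (~2%, the genomic AAP rate) are
AAP-encoded.

Twenty of the 200 drugs are "planted": each of their edges picks an
AAP-encoded target with probability π = 0.5 instead of the ~0.02
background. Planted drugs also share a block of substructure keys, so
substructure-mediated diffusion preferentially routes resource among
them — this is what makes the experimental-plus-predicted condition flag
at least as many planted drugs as the experimental-only condition, the
qualitative behavior of interest. All generators are bit-reproducible
under a fixed seed, and truth labels are validated against the emitted
data at generation time.

What the generator does **not** emulate: real chemistry (SMILES are a
small cycle of simple valid structures, used only to exercise the
standardization path), correlated target families (π applies per edge
independently), gene nomenclature (synthetic G-number tokens), and the
real catalogue's exact degree sequence. Passing recovery tests therefore
demonstrate that the statistics and plumbing behave correctly under the
stated model, not that any particular real compound is anti-aging.

The planted-recovery bound (≥ 80% of planted drugs in the top decile by
q, under the default 200-drug configuration) is a seeded regression
bound: across seeds the fraction fluctuates roughly between 0.75 and
0.90 purely from sampling noise in the planted drugs' degrees and draws,
which is the expected behavior of a binomial count of ~20.

## Problem sizes

Default analyses run at the study's stated sizes — 100,000 permutations
per compound, the 20,462/411 universe, 200-drug synthetic cohorts — and
complete in seconds thanks to the vectorized null; unit tests use smaller
permutation counts where only correctness, not Monte-Carlo precision, is
under test. The calibration experiment uses 2,000 null drugs at 10,000
permutations (the nominal-level fraction is governed by the discreteness
of the null, not by permutation resolution).

## Known limitations

- No modeling of activation vs. inhibition: a compound antagonizing an
  AAP scores identically to one agonizing it.
- Organism matching excludes strain-suffixed records.
- Gene symbols are compared literally; cross-nomenclature lists need
  pre-harmonization.
- The diffusion's normalization conventions (which class α favors,
  whether to renormalize after hub damping) follow the documented
  defaults and switches; other published variants may rank differently.
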