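# Methods

## The delimitation problem

Glomeromycotan ITS sequences vary so much within species that the standard
97 % OTU cutoff under-lumps at species level, while relying on tree topology
alone over-lumps toward genus level. The two-step procedure implemented in
`vt_delimit` uses three thresholds together:

- `otu_threshold = 0.03` — OTU pre-clustering distance (97 % identity). This
  only merges near-duplicates and bounds the size of the tree stage.
- `support_threshold = 50` — minimum bootstrap percentage for a clade to
  drive a merge of the representative groups it contains.
- `similarity_threshold = 0.90` — the identity envelope. A merge (and the
  fallback assignment of leftover representatives) also requires every
  between-group representative identity to be at least this value.

The published procedure does not say which of several nested supported
clades becomes a taxon. We resolve this by **bottom-up agglomeration gated
by both criteria**: clades are visited smallest-first and merge their member
groups only while the 90 % envelope holds, then the whole representative set
is visited last (it is trivially recovered by every bootstrap replicate).
The envelope is what stops supported deep clades from collapsing families
into one taxon; the support gate is what keeps 90 %-similar but
phylogenetically unsupported groups apart. Two corollaries are tested as
invariants: lowering the similarity threshold can only reduce the VT count,
and with both gates at zero everything collapses to a single VT.

The fallback compares orphans to group *representatives* (not all members),
mirroring the representative-based tree; orphans are processed in
lexicographic order and newly seeded singletons are candidates for later
orphans. OTU pre-clustering is applied uniformly to all input (the original
workflow applied it only to one genus's unidentified sequences); uniformity
simplifies the contract and only merges near-duplicates. With three or fewer
representatives no tree is built and grouping is similarity-only.

## Alignment and identity conventions

All thresholds are fractions of identical columns in a global
Needleman–Wunsch alignment (match 1, mismatch −1, linear gap −2; the
thresholds, not the raw scores, carry the analysis). Identity excludes
terminal-gap columns; each internal gap column counts as one difference
(`each-gap`), with a `one-gap-per-run` alternative. Ties in the traceback
prefer diagonal, then up, then left, making alignments deterministic.
Distances are `1 − identity`; they need not satisfy the triangle inequality
and no code assumes they do. The multiple alignment of representatives is
center-star (center = minimal distance-matrix row sum, "once a gap, always a
gap"), which is exact to degap and cheap at representative counts.

## Tree inference

The delimitation rule consumes only clade memberships and bootstrap
supports, never likelihoods, so tree inference is distance-based:
Jukes–Cantor corrected distances d = −(3/4)·ln(1 − 4p/3) on the columns
where both rows are ungapped (saturating at 5.0 when p ≥ 0.75), and
Saitou–Nei neighbor joining. NJ is exact on additive matrices — which makes
it fully testable against a generating-tree oracle — and ties in the
Q-criterion break on the smallest leaf-label pair. Negative branch length
estimates are clamped to zero with the deficit shifted to the sibling edge
(Kuhner–Felsenstein convention). GTR-style corrected distances are a noted
extension point. The bootstrap resamples alignment columns with replacement
(default 100 replicates, configurable; the replicate count is not prescribed
anywhere authoritative) and scores recovery of each reference bipartition.
Bipartitions are canonicalised as the side not containing the smallest leaf
label, so the set is invariant to input order; trees are unrooted and clade
enumeration takes the smaller side of each split.

## Synthetic data: what it emulates and what it does not

`generate_taxa` plants K taxa: ancestors are drawn by mutating a common root
at rate `inter_div` per ancestor and accepted only when every pair differs
at ≥ `inter_div` of sites (bounded retries, then an explicit failure);
members are the ancestor mutated i.i.d. per site at `intra_mut`,
substitutions uniform over the three alternative bases — matching the JC
correction used downstream. Abundances default to geometric (p = 0.5), so
singleton and doubleton taxa occur as they do in real sequence corpora.
Defaults (400 bp, intra 0.02, inter 0.20) put within-taxon identity near
0.96 and between-taxon identity far below 0.90, respecting both published
cutoffs with margin. Indels are off by default to keep planted identities
analytically controllable; an indel-enabled fixture exercises the aligner.
The generator does not emulate ITS secondary structure, chimeras, copy-number
variation within spores, or alignment-hostile repeat regions — passing tests
therefore validate the machinery and its thresholds, not the biological
fidelity of any particular corpus.

`attach_metadata` plants endemism exactly: per scheme,
`round(endemism_fraction·K)` taxa get one label for all members, the rest
are forced onto ≥ 2 labels. Spread taxa need ≥ 2 members, so singleton taxa
are unavoidably endemic; the generator raises rather than silently missing
the target. Sample origin defaults to `root` for every sequence so planted
fractions survive the root-origin filter applied to host-linked analyses.

`generate_path_data` draws exogenous variables as independent standard
normals and each endogenous variable as its planted linear combination plus
Gaussian noise scaled to unit population variance, so the planted
coefficients are standardized by construction; it rejects cyclic structures
and coefficient sets implying variance > 1.

## Occurrence filters

Controlled vocabularies: functional groups {grass, forb, woody}; ecosystems
{anthropogenic, forest, grassland, shrubland, successional}; six continents;
eight biogeographical realms; Köppen–Geiger climate types {arid, equatorial,
polar, snow, warm temperate}. Supercontinents: North America and Eurasia →
Laurasia; Africa, South America, Oceania → Gondwana; the Indo-Malay realm →
Gondwana (India rode with Gondwana regardless of its present continent).
Sampling-sufficiency filters: a location column is kept when it has ≥ 12
sequences **or** ≥ 6 VTs (the wording reads as a logical OR, and that is how
it is implemented); a host column needs ≥ 3 VTs; the Indo-Malay realm and
shrubland ecosystem columns are always dropped as under-sampled. Sequence
counts are raw sequences, not dereplicated OTUs. Host-linked analyses use
root-origin sequences only; spatial analyses use all origins (configurable).

## Community statistics

Rarefaction subsamples without replacement (default 1000 iterations) and
reports percentile 95 % intervals; the hypergeometric closed form is
computed alongside and the randomized mean is required to track it within
3 Monte-Carlo standard errors. NMDS minimizes Kruskal stress-1 with
isotonic-regression disparities and Guttman majorization; start 0 is
classical (Torgerson) scaling and the remaining 19 starts are random, so
exactly embeddable inputs converge immediately; a step that would increase
stress reverts and stops the start, making the stress sequence monotone.
Stress tolerance is 1e-6; ordination is on counts by default (presence is a
caller choice upstream). The Mantel statistic is the Pearson correlation of
condensed distance vectors; the null permutes rows and columns of the second
matrix simultaneously, p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), one-sided
positive by default (the hypothesis is positive coupling), 999 permutations.
Permuting a distance matrix permutes its condensed entries, so the permuted
statistic is computed by re-indexing pre-standardized vectors — exact, not
approximate. OLS p-values use the exact t/F distribution; no multiple-testing
correction is applied anywhere. The host-range regression counts distinct
host orders (x) against distinct locations (y) per VT; locations, not
continents, are the geographic unit (a caller-configurable choice).
Composition-similarity regressions use Bray–Curtis *similarity* (1 − BC) on
both axes.

## Path model

Variables are first-principal-component scores of per-location composition
tables (counts row-normalised to proportions before centering; PC1 sign
fixed so the first lexicographic feature loads nonnegatively — coefficient
signs are otherwise arbitrary). Estimation is per-equation standardized OLS,
which coincides with full-information ML in the population for recursive
models with observed variables and is closed-form, hence exactly testable.
Indirect effects come from path tracing ((I−B)⁻¹ − I), so
total = direct + indirect is an algebraic identity, and for a single
mediator the indirect effect is exactly the product of its two paths. Fit
indices use the ML discrepancy F = ln|Σ̂| + tr(SΣ̂⁻¹) − ln|S| − p with
Σ̂ = (I−B)⁻¹Ψ(I−B)⁻ᵀ (exogenous block of Ψ free at its sample values,
endogenous residuals 1 − R²): χ² = (n−1)F, df = p(p+1)/2 − free parameters,
RMSEA = √(max(χ²−df,0)/(df(n−1))), TLI against the independence baseline.
The default six-variable structure with all nine paths free is saturated
(df = 0, χ² = 0 identically); fit indices are then flagged and p/TLI are
undefined. Degrees of freedom are always reported explicitly.

## Problem sizes and numerical choices

Test and acceptance runs use planted corpora of 5–20 taxa at 400 bp
(tens of sequences), 100 bootstrap replicates, 999 Mantel permutations,
1000 rarefaction iterations, and n = 5000 per path-model fit — sizes chosen
so every stochastic check has comfortable statistical margin while a full
run stays interactive. Coefficient-recovery tolerance (±0.03 at n = 5000)
is ~2.2 sampling standard errors per estimate, so recovery is scored per
effect estimate. Ties everywhere (cluster merges, medoid choice, NJ pairs,
orphan processing) break on lexicographic labels; all randomness flows from
explicit seeds, and the end-to-end pipeline writes byte-identical artifacts
for a fixed master seed.

## Known limitations

- No maximum-likelihood tree search or rate heterogeneity; NJ/JC69 is a
  deliberate substitution justified because only memberships and supports
  are consumed.
- Linear gap costs only; no k-mer prefilter, so distance matrices are
  quadratic in input size — fine for representative-scale inputs, not for
  hundreds of thousands of reads.
- Identity-based distances are not metric; nothing downstream assumes they
  are.
- The synthetic generator's independence assumptions (sites i.i.d., labels
  drawn per taxon) make recovery easier than in real corpora with chimeras,
  misannotation and uneven sequencing effort.
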