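# Methods

## Quantification model

Mapped mRNA read counts are compared at the level of Pfam domain
families because the communities under comparison share functional
categories, not genes. For family *i* in community *A*:

- per-gene normalization: `g/l`, reads per nucleotide of gene; counts
  scale with gene length under shotgun read mapping, so dividing by
  length makes genes comparable. No per-kilobase or per-million scaling
  is applied — depth is handled separately.
- collation: `p_iA = Σ g/l` over the genes annotated to family *i*. A
  gene carrying several domains contributes its full normalized count to
  each of its families (domains are not fractionally attributed, so a
  multi-domain gene legitimately appears in every family it supports);
  genes with no annotation are excluded.
- size factors: `S_A = median_i p_iA / (Π_C p_iC)^{1/m}` over the
  families with positive expression in all m communities (zero geometric
  means are dropped, following the median-of-ratios convention). The
  median of an even-length set is the mean of the central pair — which is
  why the exact reciprocal identity below holds only for odd counts. The
  median runs over **all** annotated families, not only the targeted
  GH/CBM list: size factors measure depth, and restricting them to the
  families under test would confound depth with the biology being tested.
- normalized expression: `P_iA = p_iA / S_A`; the expressed-gene count
  `n_iA` counts annotated genes with ≥ 1 mapped read (the same
  definition as the permutation test's sampling pool, so group sizes and
  pools are consistent).

With two communities and an odd number of usable families, the two
medians select one reciprocal ratio pair, so `S_A·S_B = 1` in real
arithmetic. In floating point the product is within a few ulp of 1 for
arbitrary inputs and exactly 1 when the per-family ratios are exactly
representable; the test suite asserts both forms. The implementation
uses `sqrt(p_A p_B)` directly in the two-community case to keep
dyadic-exact inputs exact.

## Pseudo-family permutation test

The null asks: does family *i*'s expression difference exceed what
random gene groups of the same sizes produce? Sampling pools hold the
size- and length-normalized values `g/l/S` of every annotated gene with
a nonzero count — including genes annotated only to non-target families,
since the null is about arbitrary gene groups. Each pseudo-family is a
uniform draw *without replacement* of `n_iA` genes from pool A and
`n_iB` from pool B; the difference of their sums is one null draw;
10,000 draws per run (default), 3 runs (default), and the reported
p-value is the mean of the per-run values.

The p-value is the **fixed-direction** tail `p = P(D_pseudo ≥ D_obs)`
with `D_obs = P_target − P_other`, where the *target* community (the one
whose overexpression is being probed, e.g. the thermophilic culture in a
thermotolerant-enzyme screen) is a parameter. Families overexpressed in
the other community drift toward p = 1 rather than becoming significant;
under the null the p-value is uniform by probability-integral transform.
Add-one smoothing `(b+1)/(N+1)` keeps p strictly positive. No
multiplicity adjustment is applied to these p-values — the analysis is a
discovery screen in which false negatives are costlier than false
positives — and the significance threshold is an inclusive 0.10.

Families with zero expression in both communities are reported as "not
detected" with no p-value. If a family's expressed-gene count somehow
exceeded its pool, the group size is capped at the pool size.

Implementation note: within one run, the sampler draws one random
permutation per community per replicate and reads every family's group
sum off the permutation's prefix sums (the prefix of a uniform random
permutation is a uniform without-replacement draw). Each family's null
marginal is therefore exact; what is shared is randomness *across*
families within a run, a deliberate trade for tractability at
10,000 replicates × many families. Averaging the 3 independent runs
dilutes the shared-randomness coupling. `permutation_null` provides the
fully independent reference sampler, and the test suite checks both
paths against exhaustive enumeration on small pools.

### Calibration and its limits

On data where genes are exchangeable across families (no family-level
expression structure), the p-value is uniform and the type-I error at
0.10 is 0.10 — the acceptance suite verifies this on 500 simulated null
datasets. When families have their own baseline expression levels, the
null hypothesis "this family behaves like a random gene group" is false
even without any between-community difference: a family's two sums share
one baseline while pseudo-groups mix baselines, which *widens* the null
and makes the test conservative for mid-range differences (measured
type-I ≈ 0.02 under the structured generator). That conservatism is a
property of the published test itself, not of this implementation.

## Pooled-duplicate negative-binomial test

The second method adapts the no-replicate mode of the median-of-ratios /
NB framework. Inputs are the per-family **summed raw mapped read
counts** (multi-domain genes counted once per family, rounded
half-to-even if a caller supplies non-integers); length normalization is
deliberately absent here because the NB model describes read-count
noise, and depth is handled by the size factors estimated upstream
(single source of truth — no internal re-derivation).

With one library per community, the two size-normalized counts
`z_j = k_j/S_j` are treated as duplicates. Per family: common-scale mean
`q = (z_A+z_B)/2`, sample variance `w = (z_A−z_B)²/2`, shot-noise term
`q·ξ` with `ξ = (1/S_A+1/S_B)/2`, and excess `w − q·ξ ≈ α q²`. The
single dispersion α is the **median** of the per-family moment estimates
`excess/q²` over families with positive excess (clamped at 0; Poisson
when no family shows excess). The median embodies the method's stated
assumption that most families are not differentially expressed — the
same logic as median-of-ratios size factors — so a handful of strongly
discordant families cannot inflate α enough to excuse their own
discordance, while a majority of discordant families still drives α up
(the acknowledged overestimation under assumption violation, which costs
power, not type-I error).

Each family is then tested conditionally on its total `k_S = k_A+k_B`:
under the null both counts share the per-unit rate
`q₀ = (k_A/S_A + k_B/S_B)/2`, marginal means `q₀S_A`, `q₀S_B`, variance
`μ + αμ²`. The two-sided p-value sums the joint probabilities of all
splits no more probable than the observed one (ties included via a
1e-12 relative tolerance absorbing order-of-evaluation rounding),
normalized by the total over splits, computed in log space for
stability. At α = 0 with equal size factors this reduces exactly to the
two-sided conditional binomial(k_S, ½) test. P-values are
Benjamini–Hochberg adjusted; the consensus significance call requires
both the mean pseudo-family p and the adjusted NB p at or below 0.10.

## Descriptive layers

- **Sequencing metrics**: rRNA% = (total−mRNA)/total, mapped% =
  mapped/mRNA, lignocellulolytic% = target-family reads/mapped, rounded
  to one decimal (two for the last) as conventionally printed.
- **Composition**: a family's share of the lignocellulolytic GH
  transcriptome, denominated over the GH-category target families only
  (CBMs are binding modules, not hydrolases, and are reported
  separately). Shares are size-factor-free.
- **Taxonomy attribution**: genus (and phylum roll-up) shares of each
  family's normalized transcripts; the dominant list is the shortest
  descending-share prefix strictly exceeding 50%, ties broken
  alphabetically for determinism.
- **Dominant genes**: the shortest prefix of genes, by descending
  normalized count, covering ≥ 90% (configurable) of a family's
  expression.
- **Rarefaction**: expected distinct expressed genes at subsampled
  depths, simulated by multivariate-hypergeometric draws from the
  integer mapped-read multiset (counts, not normalized values — the
  subsampling models resequencing at lower depth). The hypergeometric
  closed form `E = Σ_g (1 − C(T−c_g, m)/C(T, m))` serves as the test
  oracle only.

## Synthetic data generator

The generator emulates the comparative design the method exists for:

- two communities with **disjoint gene sets** (a `shared_gene_fraction`
  knob exists, default 0) realizing **one functional profile**: the
  genes-per-family allocation (Dirichlet-multinomial, ≥ 2 genes per
  family per community) is drawn once per dataset, so unplanted families
  are exchangeable between communities — the property that makes them
  scoreable as true nulls;
- gene lengths log-uniform on [300, 3000] nt, drawn per community; the
  count mean scales multiplicatively with length so that length
  normalization is genuinely exercised (a property test checks the
  length trend disappears after normalization);
- per-family baseline expression log-uniform on [5, 100] expected reads
  per gene (at 1 kb, unit depth), shared by both communities; planted
  families' baselines are floored at 25 so each planted family carries
  ≥ 50 expected reads where it is *not* overexpressed;
- NB counts with dispersion α = 0.05 (modest biological overdispersion;
  0 gives Poisson), library-size factors √4 and 1/√4 (the default 4×
  ratio reproduces size factors near 2 and 0.5, echoing the regime the
  method was built for);
- default planted effects: folds 130, 50 and 30 on GH48 (PF02011),
  CBM33 (PF03067) and CBM2 (PF00553), favoring the thermophilic-analog
  community — the fold regime in which consensus detection is expected;
- default target list: the 30 of the 33 built-in GH/CBM families that
  are detectable at all (the three families with no expression anywhere
  are left out of the simulation but still reported as "not detected" by
  the pipeline);
- taxonomy: community-specific genus pools with per-family Dirichlet
  shares (overridable per family), phyla implied by genus.

What the generator does **not** emulate: rRNA contamination and
filtering, read mapping ambiguity, assembly/annotation errors,
inter-gene correlation within operons, and community structure beyond
the family level. Passing tests therefore validate the statistical
machinery under the model's own assumptions, not robustness to upstream
bioinformatics artifacts.

## Problem sizes and numerical choices

Simulation-based checks use deliberately scaled problem sizes chosen to
make their statistical targets measurable: 600 genes per community and
10,000 replicates × 3 runs for end-to-end recovery over 100 datasets;
150-gene communities with 1,000 replicates for the 500-dataset null
calibration; 200 subsampling replicates on ≤ 10-gene catalogs for the
rarefaction oracle. Monte-Carlo assertions use 3-standard-error bands
plus the add-one smoothing offset. Ties in discrete null distributions
are probed at midpoints between atoms so 1-ulp summation differences
cannot flip an assertion. Seeds fix every result bit-exactly; all
generators are `numpy.random.default_rng` children of one user seed.

## Known limitations

- The pseudo-family test is conservative when families have strong
  baseline structure (see calibration above) and its power for a family
  is limited by the chance of drawing that family's own dominant genes
  into pseudo-groups — with few annotated genes overall, even a 130-fold
  family can sit near p ≈ 0.1.
- The single-α dispersion model is a deliberate simplification of
  mean-dependent (local-regression) dispersion fits; with ~30 families
  there is little information for anything richer.
- Exactly two communities are supported by the tests (the size-factor
  estimator generalizes to m).
- P-values from the two methods are combined only by the AND rule; no
  attempt is made to model their dependence.
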