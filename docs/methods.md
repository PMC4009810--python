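# Methods

## Model and conventions

**Tree model.** A rooted phylogeny with non-negative branch lengths in
arbitrary units (substitutions/site or unit-free). A branch is identified by
its child node; the descendants of a branch are the tips below that node.
A stem branch above the root is allowed and is stored as the root node's
length. Polytomies are allowed; trees are not assumed ultrametric and no
index here requires it.

**Rooted PD.** PD of a tip set is the summed length of all branches on the
union of the tips' root paths, *including* the stem when present. The rooted
convention is used because the deep branch below a clade is part of what
conservation of that clade preserves; an MRCA-spanning variant is available
via `pd_value(..., rooted=False)` for users who want the unrooted quantity,
but none of the packaged examples use it.

**Extinction model.** Each tip carries an extinction probability, either
explicit or converted from its IUCN category by the pessimistic scheme
(CE 0.99, E 0.9, V 0.8, NT 0.4, LC 0.2). DD and NE have no conversion;
tips in those categories must be given an explicit probability or a
model-level default — they are never silently dropped, because removing a
tip changes every branch-loss product it participates in. Extinctions are
assumed independent across species. This is the standard assumption behind
EDGE and expected-PD arithmetic; it is optimistic for co-distributed
species (e.g. a clade confined to one threatened region), where true deep-
branch loss probabilities are higher. Correlated extinction models are out
of scope.

## Expected PD and conservation actions

Branch loss probability q = ∏ p over descendants; expected PD loss
Σ L·q over a scope (whole tree, a labelled clade — its stem plus all
branches below, with more ancestral branches treated as secure — or an
explicit branch list). The expected-PD change of an action revising some
tips' probabilities is Σ L·(q⁰ − q¹), which only involves branches whose
descendants intersect the revised tips.

**Display rounding.** All products are kept at full precision internally.
Worked summaries in this literature conventionally present per-branch
probabilities at two decimals (0.99³ = 0.970299 shown as 0.97); the
`prob_decimals` argument reproduces that convention (82.29 for the
Caribbean clade; 64.67 for the move-to-NT improvement). Full precision
gives 82.30 and 64.54 respectively; both conventions are printed in
`examples/02`, and tests pin each explicitly. One published component sum
(13.2 + 6.2 + 4.7 = 24.1) cannot be reproduced under any consistent
rounding (the third component is exactly 4.8); the package reports the
full-precision 24.16 and the example flags the discrepancy.

**EDGE scores.** Credit per root-path branch is L/n (default, standard
evolutionary distinctiveness) or the literal 1/n count mode, times the
species' extinction probability. EDGE ignores the threat status of
co-descendants; the nasuta/pichoni fixture demonstrates the resulting rank
reversal against expected-PD gain, which accounts for complementarity.

## Risk analysis

There is no single formula for phylogenetic risk analysis; the implemented
workflow is: nominate worst-case loss thresholds, compute P(loss ≥ t) from
the loss distribution, and compare actions by how they move those tails
alongside their expected-PD gain (`compare_options_risk`).

The exact distribution enumerates all 2ⁿ extinction outcomes for the n tips
in scope (default cap n ≤ 20), processing outcomes in blocks of 2¹⁶ with
vectorised branch-subset tests, so the outcome set is never materialised as
explicit subsets. Outcomes whose losses agree to 1e−12 are merged;
zero-probability outcomes are dropped. Monte Carlo (default 100 000
replicates) requires a seed — reproducibility is a contract, not an option —
and reports a binomial standard error per queried tail. The exact mean
matches `expected_pd_loss` to 1e−9, tying the two modules together in the
test suite.

## Spatial heterogeneity

**DPD / HPD1.** A branch is represented in a locality if any tip occurring
there descends from it. DPD(i,j) is the total length (default) or count
(`weighted=False`) of branches represented in exactly one of the two
localities — a symmetric-difference measure, hence a pseudometric. HPD1 is
the mean DPD over unordered distinct locality pairs; including self-pairs
would only rescale it by a constant, so they are excluded. Length weighting
is the default because the PD framework counts features by branch length;
the bare count is kept as an option.

**HPD2.** With per-branch range rᵢ (cardinality of the union of descendant
locality sets) and T = Σ Lᵢrᵢ, HPD2(q) = (Σ Lᵢ(rᵢ/T)^q)^{1/(1−q)}, with the
closed-form limit exp(−Σ Lᵢ pᵢ ln pᵢ) at q = 1 (never numeric evaluation
near the pole). Branches with empty range are excluded. At q = 0 the index
equals PD of the represented branches; equal ranges collapse it to PD at
every q; it is scale-invariant in the ranges and non-increasing in q. The
union abundance is the substantive choice: a species sharing all its
ecosystems with its sister adds nothing to their common branch's range,
which is what makes HPD2 sensitive to rare-branch decline. The Chao-style
summed abundance is retained behind `abundance_mode="sum"` for comparison.

## Fixtures and synthetic data

Packaged fixtures reconstruct the worked examples from their printed
constraints; where a figure omits terminal branch lengths, those terminals
are set to 0 so exactly the printed lengths contribute, and where lengths
are entirely unprinted (nasuta/pichoni) they are placeholders of 1 with
tests asserting only probabilities and rank order. Non-focal species names
are synthetic placeholders (`A_sp*`). Caribbean ecosystem occupancies are
the minimal assignment consistent with the printed counts (cervicornis in
8 ecosystems; the palmata+prolifera branch union 8; the stem union 9).

The generator produces Yule topologies (uniform lineage splitting) with
Exp(1) branch lengths; IUCN categories are drawn with the observed Acropora
category frequencies (CE 1.2 %, E 1.7 %, V 28.3 %, NT 12.7 %, rest LC —
the data-deficient/not-assessed mass is folded into LC so every synthetic
tip yields a usable probability); each tip occupies a uniform 1..k of k
localities (default 10). Identical seeds give byte-identical fixtures.
Synthetic trees emulate the *shape* of the study system, not real coral
occupancy structure (no spatial autocorrelation, no range cohesion among
relatives), so property tests passing on them demonstrate algebraic
correctness, not realism of any particular empirical conclusion.

Property suites use 8–20 tips so the brute-force oracles (all-subset path
unions, full outcome enumeration) stay effectively instantaneous.

## Known limitations

- Independence of extinctions (see above); no correlated or spatially
  coupled models.
- No rarefaction/standardisation of PD, no abundance data from individuals
  or biomass, no confidence intervals on HPD2.
- No tree inference: trees arrive as Newick with branch lengths already
  estimated.
- Portfolio optimisation over many actions under a budget is out of scope;
  `rank_by_expected_pd_gain` and `compare_options_risk` compare a supplied
  list of options.
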