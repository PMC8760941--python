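# Methods

## The inference problem

Given gene trees for a receptor family sampled from three independent
parasite–host species pairs, nonhost relatives, and at least one reference
outgroup species, the question is whether losses of the *same* ortholog
recur across the independent parasite lineages more often than expected if
each lineage lost genes independently. The chain is: ortholog clusters →
per-lineage loss calls → marginal loss probabilities → product null →
exact binomial test.

## Ortholog clusters

A cluster is a **maximal focal-only clade**: a clade whose leaves all
belong to non-reference species and whose parent's subtree contains at
least one reference leaf. This is the parameter-free formalization of
"label a clade as an orthologous cluster when a reference-species receptor
is its outgroup": maximality forces a reference gene immediately outside
the clade, and the reference leaves under the parent (outside the cluster)
are its *anchors*. Every focal leaf belongs to exactly one cluster, so raw
per-species counts partition the focal leaves; a mixed clade (reference
inside) is never a cluster — its focal leaves fall into smaller maximal
clades.

Before clustering, internal edges with support strictly below the
threshold (default 0.7, the conventional bootstrap cut-off) are contracted
into multifurcations. Nodes without a support value (root children,
unlabeled nodes) are **retained**: absence of a value is not evidence of a
weak edge. Support dialects are normalized at parse time — if any support
exceeds 1, the whole tree is treated as percent-scaled and divided by 100 —
so the 0.7 threshold means the same thing for FastTree and IQ-TREE
inputs.

Species-specific expansions are then collapsed: every maximal
single-species clade becomes one representative leaf (the
lexicographically smallest gene id, for determinism), and at a
multifurcation all single-species child subtrees of the same species are
merged into one. Any merge marks a *gain* for that species in that
cluster, so `gain[s] ⇔ raw_count[s] > count[s]` holds by construction.
Manual curation — the paper-world practice of splitting/merging clusters by
eye — is replaced by an explicit, auditable override table (gene →
cluster); moved genes carry their collapse-group membership, so counts
recompose exactly (a merged cluster's counts are the sums of its parts).

Subfamily assignment is a majority vote over anchor labels, ties broken by
the anchor topologically closest to the cluster root, then
lexicographically.

## Loss and gain calls

For each cluster and each parasite–host pair, `delta` is the post-collapse
parasite count minus the paired host count: `delta < 0` is a parasite
loss, `delta > 0` a host loss (the parasite retaining out-paralogs the
host lost), `delta = 0` no call — but the cluster still counts in the
denominator `n`, since the null and observed probabilities are defined
over all clusters. Each parasite is compared only against its own host,
never pooled hosts. Convergence means the event occurred in **all**
lineages; two of three does not qualify.

## Statistics

* **Marginals.** `m_s` = fraction of the n clusters with loss (or gain)
  for species s.
* **Null.** `p0 = ∏ m_s` over the three parasites (or hosts): the chance
  that three independent lineages hit the same cluster.
* **Test.** Two-sided exact binomial test of x convergent clusters out of
  n against `p0`, using the point-probability ("minlike") two-sidedness
  convention with relative tolerance 1 + 1e-7 — the convention of R's
  `binom.test`, delegated to `scipy.stats.binomtest`, which implements
  the identical rule (verified against brute-force enumeration for all
  n ≤ 12 grids). Degenerate nulls: p0 = 0 gives p = 1 iff x = 0;
  symmetrically for p0 = 1.
* **Interval.** Clopper–Pearson via beta quantiles:
  `low = B(α/2; x, n−x+1)`, `high = B(1−α/2; x+1, n−x)`, with the 0/1
  boundary cases pinned.
* **Power.** The exact method enumerates the rejection region
  `R = {j : p(j; n, p0) ≤ α}` and sums the alternative pmf over it; the
  simulation method draws B ≥ 10⁴ binomials. Both are exposed and reported
  side by side because published power values for this design rarely state
  their method; exact rejection-region power at the observed effect size
  can legitimately differ from other conventions (here, for the
  odorant-receptor case, exact power is ≈ 0.99 where ≈ 0.88 was published;
  the cross-family comparison at equal n reproduces qualitatively, ≈ 0.37
  vs the published 0.35).
* **Enrichment.** Per-subfamily exact binomial tests of convergent-loss
  counts against the **family-wide** null `p0` (the shared-null reading of
  a table whose all-receptors row carries the same p as the main test),
  Benjamini–Hochberg adjusted across subfamilies. The adjustment procedure
  is BH step-up throughout (the source material says only "FDR"/"P_adj");
  it is delegated to `statsmodels.multipletests` and cross-checked against
  a hand-rolled step-up oracle in the tests.
* **Proportion tests.** Pearson χ² on the 2 × k success/failure table,
  Yates-corrected only for k = 2, matching R's `prop.test`.

## Selection post-processing

One selection record per cluster (test branches = all parasite branches).
Records with any branch dN/dS > 10 are excluded before FDR control, as
unreliable fits. Clusters with k < 1 and FDR < 0.05 are relaxed; k > 1 and
FDR < 0.05 intensified. Loss categories count lineages with parasite loss
(none / one / multiple); k distributions are compared with a two-sided
Wilcoxon rank-sum test using midranks, exact permutation enumeration when
there are no ties and n₁·n₂ ≤ 10⁴, otherwise a normal approximation with
tie and continuity corrections. The reported W is the Mann–Whitney U of
the first group (its rank sum minus the minimum), so 0 ≤ W ≤ n₁·n₂. An
alternative design with one record per lineage pair is representable by
suffixing cluster ids; convergent relaxation then requires all of a
cluster's records to pass.

## Simulator

Each family starts as a single copy at the root of an ultrametric,
unit-depth species tree with three parasite–host pairs (each pair
splitting 0.2 before the present, so parasite terminal branches are
comparable), two nonhosts, and a reference outgroup on a depth-1 branch.
Copies duplicate at rate λ and are lost at rate μ per copy per unit
length; parasite terminal branches multiply μ by `parasite_multiplier`
(ordinary families) or `convergent_multiplier` (the designated
convergent-target fraction f of families — genes whose function parasites
have abandoned). The reference terminal branch has loss rate 0, so every
family retains ≥ 1 anchor, mirroring curated data in which every cluster
has a reference outgroup.

Defaults — λ = 0.4, μ = 0.3, multiplier 5, target multiplier 40, f = 0.1,
n = 300 families — were fixed once so that baseline per-parasite marginal
cluster-loss is ≈ 0.25 and per-host ≈ 0.04 on this tree, the regime of
real odorant-receptor repertoires (parasite marginals whose product is
≈ 0.016, host product ≈ 8 × 10⁻⁵); target families lose each parasite
copy with probability ≈ 0.9. Supports are fixed at 1.0 by default or drawn
iid Beta(a, b) per internal node; gene-tree error is modeled *only*
through support noise followed by collapsing, not topology scrambling,
because the method consumes supports (a `topology_noise` hook exists but
is deliberately unimplemented). All randomness derives from
`(seed, family_index)` pairs, so datasets are byte-identical across runs.

The truth table records raw tip counts and a genealogy-level analogue of
post-collapse counts (maximal single-species clades in the true
genealogy), which is what loss calls are defined on — a species-specific
duplication is not a countable ortholog lineage. What passing end-to-end
tests show is that the pipeline's tree surgery, clustering, collapsing and
calling are exact on clean data and well-behaved under support noise; they
do **not** show robustness to annotation error, assembly artifacts,
alignment error, or wrong tree topologies, none of which the generator
emulates.

## Numerical and design notes

* Strict inequality at the support threshold: 0.7 itself is retained.
* Edge contraction adds the contracted edge's length to its children,
  preserving root-to-leaf path lengths (lengths are not used downstream).
* Rerooting stores supports per unrooted bipartition and reassigns them
  after the topology change, so supports never migrate to a different
  split; if a binary root's two child labels disagree (they describe the
  same split), one value is kept.
* Clusters with zero copies for some focal species are scored for every
  lineage (absence = count 0); there is no attempt to distinguish "never
  ancestrally present" — the denominator n is the full cluster count.
* Convergence-test p-values on null data are conservative (discrete test,
  x typically 0 with p = 1), so calibration is asserted as a bound on the
  type-I error rate at α = 0.05 rather than distributional uniformity.
* Problem sizes in the validation suite — 200 replicates of 300 families
  for detection power, 500 for type-I error, 200 random trees against the
  exhaustive clustering oracle, 10⁴ draws for CI coverage — keep the whole
  suite under a minute while leaving Monte-Carlo error well below the
  asserted margins.

## Known limitations

* The clustering rule assumes a rooted tree whose reference genes are
  outgroups to focal clades; a badly misrooted tree yields fragmented
  clusters rather than an error.
* Curation overrides recompute counts from collapse groups, which is exact
  for merges and splits of existing groups but cannot re-run tree-based
  collapsing across newly adjacent genes.
* Host-vs-nonhost turnover comparisons reuse the same call machinery via a
  custom pairing configuration but ship without dedicated statistics.
* Gain convergence is flagged and reported, but no enrichment test is
  defined for gains.
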