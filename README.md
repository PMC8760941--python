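# convloss

Inference of **convergent gene-family loss** across independent
parasite–host lineage pairs, from gene trees.

Obligate social parasites — for example slave-making ants, which outsource
foraging and brood care to workers of closely related host species — tend
to shed genes whose functions their lifestyle has made dispensable.
Chemoreceptor families (odorant receptors *Or*, gustatory receptors *Gr*)
are a prime target: they expand and contract rapidly, and losses of the
*same* ortholog in several independently evolved parasite lineages suggest
the loss itself is a repeatable evolutionary response. `convloss`
implements the full inference chain for detecting such convergence from
gene trees of three (or more) parasite–host pairs plus nonhost relatives
and a reference outgroup species:

1. **Tree preparation** (`convloss.treeio`) — newick parsing with
   FastTree/IQ-TREE-style supports (0–1 or 0–100 dialects auto-detected),
   rooting on a designated outgroup (e.g. Orco for *Or* trees) with
   supports kept on their bipartitions, and contraction of weakly
   supported edges (default: support < 0.7) into multifurcations.
2. **Ortholog clustering** (`convloss.clustering`) — every maximal clade
   consisting solely of focal-species genes, anchored by the reference
   genes in its sister subtree(s); species-specific expansions
   (in-paralogs, including those exposed by multifurcations) are collapsed
   to one representative and flagged as *gains*; optional manual-curation
   overrides and ancestral-subfamily assignment via the anchors.
3. **Gain/loss calling** (`convloss.gainloss`) — per cluster and lineage,
   `delta = n_parasite − n_host` on post-collapse counts; `delta < 0` is a
   parasite loss, `delta > 0` a host loss; an event is *convergent* when
   it occurred in every lineage.
4. **Convergence statistics** (`convloss.convstats`) — per-species
   marginal loss probability `m_s = (clusters with loss in s)/n`; the null
   probability of convergent loss `p0 = ∏ m_s` over the parasites (or
   hosts); a two-sided exact binomial test of `x/n` against `p0`
   (point-probability convention, as in R's `binom.test`), Clopper–Pearson
   95% CI, exact rejection-region and simulation power, subfamily
   enrichment with Benjamini–Hochberg adjustment, and χ² tests for
   equality of proportions.
5. **Selection post-processing** (`convloss.selection`) — ingestion of
   per-cluster selection-intensity results (k, LRT p, max dN/dS) from a
   branch-model test such as HyPhy RELAX, exclusion of unreliable fits
   (dN/dS > 10), FDR control, relaxed/intensified flags, and Wilcoxon
   rank-sum comparisons of k across loss categories.
6. **Simulator** (`convloss.simdata`) — a birth–death gene-family
   generator along a species tree with three parasite–host pairs, elevated
   loss on parasite terminal branches, a designated convergent-target
   subset, guaranteed reference anchors, and optional Beta-distributed
   support noise, plus a per-family truth table for end-to-end validation.

## Worked example

Simulate 300 gene families under the default study conditions (a tenth of
families are convergent targets with strongly elevated parasite loss) and
run the full pipeline:

```sh
convloss simulate --n-families 300 --seed 7 --out sim
convloss all --trees sim/gene_trees.nwk --mapping sim/mapping.tsv \
    --roles sim/roles.yaml --anchors sim/anchors.tsv --out out --seed 7
```

which prints

```
clusters: 285  convergent parasite losses: 18/285 (p0=0.0339, p=0.01251)
reports written to out
```

285 of the 300 simulated families kept at least one focal-species gene and
were recovered as ortholog clusters. 18 clusters lost parasite orthologs
in **all three** lineages; under independence the expected probability is
the product of the three parasite marginals (0.340 × 0.305 × 0.326 =
0.0339, i.e. ≈ 9.7 expected clusters), and the exact binomial test rejects
independence (p = 0.0125). `out/convergence.json` carries the full result:
observed probability 0.0632 with 95% CI [0.0379, 0.0980], exact power
0.721 at the observed effect size, and the host-side counterpart (0
convergent host losses; host null 3.3 × 10⁻⁵ — host losses are too rare
for convergence to be expected). `out/clusters.tsv`, `out/calls.tsv` and
`out/enrichment.tsv` hold the per-cluster counts, per-lineage calls, and
per-subfamily enrichment.

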