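# Methods

## Scope and model

`phyloflora` implements a phylofloristic analysis: regional taxon checklists
are bound onto a time-calibrated backbone phylogeny, and the resulting
analysis trees are used to quantify (i) within-flora phylogenetic structure
and (ii) between-flora phylogenetic beta diversity, at family, genus and
species rank, optionally within geographical-element subsets. All metrics
are presence/absence based; abundances are not modelled.

### Within-flora structure

For a community (the taxa of one region) with patristic distance matrix
`d`, the package computes

* **MPD** — the mean of `d` over all unordered pairs of community members;
* **MNTD** — the mean, over members, of the distance to the nearest other
  member.

Both are compared to a tip-shuffle null: the tip labels of the pool-pruned
phylogeny are permuted `n_perm` times (default 999) and the metrics
recomputed for each region from the same shuffle. The indices are the
sign-flipped standardized effect sizes

```
NRI = -(MPD_obs  - mean(MPD_null))  / sd(MPD_null)
NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)
```

so positive values mean phylogenetic clustering and negative values
overdispersion. The pool defaults to the union of all regional floras; for
element-group runs the tree and pool are first restricted to the group's
taxa, so the null asks "are this group's members in this region more
related than a random draw of the group?". One-sided permutation p-values
oriented toward clustering, `p = (#{null <= obs} + 1)/(n_perm + 1)`, are
reported next to the SES; two-sided calls can be made at `|SES| > 1.96`.

### Between-flora beta diversity

* **PhyloSor** = `BL_ij / (0.5 (BL_i + BL_j))`, where `BL_i` is the branch
  length of the subtree spanning community *i* **and the root**
  (root-inclusive convention, used for every branch-length sum in the
  package) and `BL_ij` is the total length of edges lying in both spanning
  subtrees. PhyloSor is reported raw, without a null model.
* **Dnn** — the mean distance from each taxon of one community to its
  nearest relative in the other, symmetrized as the average of the two
  directional means. Shared taxa contribute zero. Its standardized effect
  size `S.E.S. Dnn = -(Dnn_obs - mean(Dnn_null)) / sd(Dnn_null)` uses the
  same tip-shuffle null, with the same shuffle reused for every region pair
  within a permutation.

Because one shuffle relabels all communities coherently, the null preserves
between-region overlap. A consequence worth knowing: a pair of identical
regions is identical in every null draw, so its Dnn null has zero variance
and the S.E.S. is reported as missing with the degenerate flag (p = 1).
More generally, overlap and nestedness carry no signal under this null —
what S.E.S. Dnn detects is phylogenetic proximity of the two floras beyond
their shared taxa.

### Megatree grafting

Species in the checklist but absent from the backbone are bound into the
tree under three scenarios:

* **S1** (default): attach as a polytomy at the crown node of the smallest
  containing clade — the genus crown if congeners are on the tree, else the
  family crown. The pendant length equals the attachment node's age, so an
  ultrametric backbone stays ultrametric exactly, and distances among
  pre-existing tips are untouched. When the containing clade is a single
  tip, a new node is inserted halfway along that tip's pendant edge (the
  convention of the Phylomatic lineage).
* **S2**: attach at a point chosen uniformly among the clade's internal
  nodes and pendant-edge midpoints; requires a seed, which is recorded in
  the graft report.
* **S3**: attach as in S1, then re-date every node not present in the
  original backbone with the BLADJ-style smoother below. User calibrations
  (internal-node labels or tip-set MRCAs) may be supplied.

The backbone must be ultrametric for all scenarios (attachment ages are
otherwise undefined). Species whose family has no tips on the tree are
reported unplaced, excluded from the analysis trees, and logged.

**BLADJ smoothing**: every undated node is aged by even interpolation — on
a chain between consecutive dated nodes with `k` undated nodes, the age
interval is split into `k + 1` equal steps. Each node interpolates between
its nearest dated ancestor and its nearest dated descendant (breadth-first;
ties resolved toward the oldest candidate); in branching undated regions a
subsequent lift-and-clamp pass enforces monotone ages without moving dated
nodes. Edge lengths are rewritten as parent age minus child age, so every
root-to-tip path sums exactly to the root age.

**Rank-level trees**: the genus (family) tree keeps one exemplar tip per
genus (family) — the lexicographically first species of the group — pruned
of all other tips and relabelled. Polytomies are preserved throughout; no
random resolution is applied, since all metrics are distance-based and
polytomy-safe.

## Synthetic data

The generator exists so that every stage is testable without external
floras or a deposited megatree. It emulates only the statistical structure
the metrics detect:

* `simulate_tree` — forward-time constant-rate Yule or birth–death
  simulation conditioned on an exact extant tip count (extinct runs are
  restarted, extinct lineages pruned). Output is ultrametric and
  reproducible under a seed (numpy PCG64).
* `simulate_taxonomy` — families are disjoint monophyletic clades covering
  all tips, obtained by repeatedly splitting the largest clade (a clade is
  only split if each child retains enough tips to be refined into genera);
  genera refine each family the same way. Not every tree admits an exact
  partition; `simulate_dataset` rejects trees deterministically until one
  does.
* `simulate_communities` — *clustered*: sample within the smallest clade
  holding at least `size` tips; *overdispersed*: greedy maximum-dispersion
  selection, repeatedly adding the tip with the greatest total patristic
  distance to the chosen set; *random*: uniform without replacement.
  `strength` interpolates between pure structure (1) and a uniform draw
  (0). Greedy max-total-distance was chosen over farthest-point (max-min)
  selection deliberately: both are tractable stand-ins for the NP-hard
  max-MPD subset problem, but farthest-point maximizes the minimum pairwise
  distance and therefore inflates MNTD far more than MPD, giving weak NRI
  signal; the max-sum greedy drives both indices cleanly negative.
* `assign_elements` — each genus draws a super-group (default 0.5 tropical
  / 0.45 temperate / 0.05 unknown) and then a base code uniformly within
  it; species inherit their genus's code.
* `simulate_dataset` — the default three-region study: 300 tips, 12
  families x 5 genera, and regions of 40% of the pool each: one
  overdispersed ("south", strength 0.7), one random ("central"), one
  clustered ("northwest", strength 0.7). This reproduces, at desk scale,
  the qualitative layout of a sutural-zone flora of distantly related
  lineages, an intermediate flora, and a radiation-driven flora of close
  relatives.

What the generator does **not** emulate: real dispersal or vicariance,
spatial autocorrelation, rank-dependent sampling artefacts, name errors
beyond what the synonym map models, or non-monophyletic genera. Passing
tests therefore demonstrate correctness and statistical calibration of the
machinery, not that any real flora will show these effect sizes.

## Numerical choices

* Ultrametricity check: root-to-tip depths equal within relative 1e-6.
* Degenerate nulls: a null whose sd is below 1e-9 relative to its mean
  (e.g. constant up to summation-order round-off) is flagged degenerate;
  SES is reported as missing, never as infinity.
* Tie counting in permutation p-values uses the same 1e-9 relative
  tolerance, and observed values are computed through the same vectorised
  path as the nulls so that exact ties survive.
* Newick serialisation uses 17 significant digits; round trips preserve
  distances to better than 1e-9.
* All tie-breaks (exemplar choice, clade selection, taxon ordering) are
  lexicographic, making every stage deterministic given the master seed.
  The master seed expands to per-analysis streams via `SeedSequence.spawn`.
* Communities of fewer than two taxa are emitted as degenerate rows;
  requesting MPD/MNTD of a singleton raises an error at the function level.
* Taxa present in no region are dropped from matrices (they cannot affect
  any metric); infraspecific names are rejected outright.

## Problem sizes

The test suite and the acceptance script run at deliberately modest scale,
chosen as the package's own verification sizes: a 100-tip pool with 200
random 20-taxon communities for null calibration; 100 replicates of
200-tip trees with 30-taxon communities (999 shuffles each) for parameter
recovery; 50 replicates for S.E.S. Dnn sign recovery; a 300-tip three-region
study for the end-to-end pipeline. The machinery is vectorised over
permutations (patristic distances and branch-length sums reduce to
edge-incidence array algebra), so these sizes complete in seconds to a few
minutes on one core and scale to checklist-size inputs.

## Known limitations

* Family-level element vocabularies are flora-specific; the shipped family
  section is a documented placeholder to override.
* Grafting uses the taxon table (with a binomial-prefix fallback) to place
  backbone tips into genera; a backbone whose labels defy both cannot
  anchor those tips.
* The Dnn symmetrization (mean of the two directional means) is one of
  several conventions; the directional means are recoverable from the
  distance matrix if needed.
* BLADJ smoothing in branching undated regions follows the per-node
  interpolation plus clamping described above; orderings that differ from
  other BLADJ implementations can differ in those regions (chains are
  exact).
* S.E.S. values for element groups are conditional on the group's taxon
  set; they are not comparable across groups of very different size.
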