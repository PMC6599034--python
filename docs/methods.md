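# Methods

## Model

Label propagation is the harmonic-function semi-supervised scheme on an
undirected graph: labeled (seed) nodes are held at their label value and
every unlabeled node is repeatedly replaced by the degree-weighted average of
its neighbours. With a single label class (all seeds at 1, everything else
starting at 0) the iteration is monotone non-decreasing and bounded by 1, and
its fixed point is identically 1 on every component containing a seed. The
informative quantity is therefore the *finite-horizon* score: after `t`
iterations a node's `f` reflects how much diffusion reached it within `t`
steps, which decays with distance from the seed set and concentrates inside
densely connected neighbourhoods of it.

Updates are synchronous (Jacobi): each iteration reads only the previous
iteration's values. The update order of an asynchronous scheme would
otherwise make scores — and every downstream p-value — depend on node
enumeration order. Seeds are clamped throughout; unlabeled nodes start at 0
(the deterministic initialization; a random start would only add noise that
the fixed number of iterations never fully forgets); degree-0 unlabeled
nodes keep `f = 0` rather than NaN. Only `t` is exposed — there is no
convergence check, since the method deliberately runs a fixed horizon.
`harmonic_fixed_point` solves the `t → ∞` linear system exactly (optionally
with extra pinned boundary values) and exists as an oracle for the iterative
code, not as part of the workflow.

## Null model and significance

Raw `f` values are incomparable across nodes because high-degree nodes
receive more diffusion regardless of seed placement. The null model is an
ensemble of networks with *exactly* the original degree multiset, generated
by double edge swaps: a proposal replaces (a,b),(c,d) with (a,d),(c,b) and is
rejected if it would create a self-loop or duplicate edge. Full
randomization attempts `Q·|E|` swaps with `Q = 10`; attempted (not applied)
swaps are counted, which is the standard mixing convention. Propagation is
rerun with identical seeds and `t` on each random network; one shared
ensemble serves all nodes of a run.

The per-node p-value is the add-one permutation estimator
`p = (1 + #{f_r ≥ f_obs}) / (1 + n_random)`, so `p` is never 0 and BH
remains valid; ties count toward the numerator (conservative). BH step-up
runs across all unlabeled nodes; extraction thresholds on `q < α` by default
with `α = 0.05`, with raw-`p` thresholding exposed as an alternative. The
cut is strict except at `α = 1`, which admits every tested node.

A practical consequence of the add-one floor: with `n_random` permutations
the smallest attainable p is `1/(n_random+1)`, so after BH over `m` nodes a
node can only reach `q < α` if at least `m/(α(n_random+1))` nodes sit at the
floor. At sweep-scale ensembles (100–200 random networks over ~115 tested
nodes) this makes q-based extraction an all-or-nothing cliff; analyses that
need graded subnetworks at those ensemble sizes (the stability experiment
below) use raw-p extraction instead.

Partial perturbation (`perturb_network`) applies legal swaps one at a time
until the fraction of original edges replaced reaches the target; a single
swap replaces at most 2 of `|E|` edges, so the achieved fraction lies in
`[target, target + 2/|E|]`. Pathway annotations survive on original edges
that remain; rewired edges are unannotated. Fully randomized null networks
drop annotations altogether, since they are only ever propagated on.

## Enrichment

Subnetwork edges inherit their parent annotations; pathway enrichment is the
hypergeometric upper tail on the *edge* universe (`N` parent edges, `K` of
them annotated to the pathway, `n` subnetwork edges, `k` annotated), because
the subnetwork is a set of interactions and multi-annotated edges naturally
count once per pathway. A gene-based variant (nodes as the universe,
pathway membership from incident annotated edges) is exposed as
`unit="gene"`. Only pathways with `k ≥ 1` are tested and BH runs over that
family — enrichment here prioritizes among represented pathways rather than
scanning the whole annotation space.

## Network distance

With unique gene labels, the label-constrained maximal common subgraph of
two networks is exactly (node intersection, edge intersection): a common
subgraph need not be induced, so every shared label can be kept whether or
not its edges agree, and no NP-hard search arises. The exhaustive-search
oracle in the test suite exists purely to certify this reduction.
`|MCS|` counts nodes (isolated intersection nodes included), the MCS may be
disconnected, and distances compare full subnetworks (seeds plus significant
nodes). The distance is symmetric and in [0,1]; the triangle inequality is
not relied upon. Clustering uses scipy's agglomerative linkage on the
precomputed matrix (average linkage by default; complete and single
exposed), and stability between two matrices is the Pearson correlation of
their dendrograms' cophenetic distance vectors, reported as NaN when a
cophenetic vector is constant.

## Synthetic study conditions

`generate_planted_pathway_network` emulates a curated pathway resource in
pairwise-interaction form. Defaults: 4 pathways × 20 genes, each pathway a
connected random graph (uniform random recursive spanning tree plus
Bernoulli(0.25) extra edges, every intra-pathway edge annotated with the
pathway name), 15 unannotated linker edges between random cross-pathway
pairs, and 40 background nodes attached with per-node edge probability 0.02
(at least one edge each). This yields ~120 nodes and ~330 edges — large
enough for ≥100 unlabeled tests and distinct communities, small enough that
a 150–200-network ensemble runs in seconds. Pathway membership is defined
by the annotated edges themselves, exactly as it is derived when reading an
extended-SIF file.

What the generator does *not* emulate: the heavy-tailed degree distribution,
overlapping pathway membership, and annotation biases of real curated
networks, or thousands-of-nodes scale. Passing tests therefore demonstrate
correctness and qualitative behaviour of the machinery (recovery, ranking of
iteration horizons, degradation under rewiring), not quantitative
performance on a real interactome.

The drug-screen generator plants a known signal: for each planted drug,
every line mutated in either planted-pair gene draws its IC50 0.5–2 decades
below the drug's maximum screening concentration and every wild-type line
0.3–1.5 decades above. For non-planted drugs IC50s are lognormal around the
boundary, and one responder and one non-responder are forced into each
stratum, which provably blocks perfect separation for any stratification
whose mutant group is the planted group or a subset of it. Two decoy genes
are each mutated in exactly one distinct mutant line, so decoy-based strata
are strict subsets of the planted mutant group. Defaults (9 cell lines, 12
drugs, 3 planted) mirror the scale of a single-tissue screen extract.

## Characterization experiments

Recovery curves sweep an inclusive threshold grid
q ∈ {0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0}; the in-pathway rate is
`|S ∩ P \ seeds| / |P \ seeds|` and the out-pathway rate `|S \ P| / |V \ P|`
for significant set S, pathway P, node set V. Curves from different
conditions are compared at *matched* out-rate by linear interpolation with
anchors (0,0) and (1,1), and orderings across conditions are asserted with
one-sided sign tests over replicates — never as numeric values.

Within one replicate of the iteration sweep, the same seed set and the same
null ensemble serve every `t` (propagation on a given network depends on `t`
only), so the comparison across `t` is paired and unconfounded. The
perturbation sweep regenerates its ensemble from the perturbed network at
`t = 10` and judges recovery against the original pathway membership. The
stability experiment builds, per `t`, one subnetwork per seed set (two seed
sets from each of the four planted pathways, raw p < 0.05, 100-network
ensemble), computes the pairwise MCS-distance matrix, and reports the
cophenetic correlation between the clusterings at different `t`.

Test-scale defaults are deliberately reduced relative to production
defaults (ensembles of 100–200 instead of 1000, 5–10 replicates); full-scale
runs are a CLI parameter away.

## Drug-response analysis

Responder means IC50 strictly below the drug's maximum screening
concentration; equality is non-response, the conservative reading of a
boundary the dose range never crossed. Mutant/wild-type stratification by a
gene pair is mutation-in-either versus mutation-in-neither. A hit requires
*perfect*, non-overlapping separation with both groups non-empty — no test
statistic beyond the exact rule, by design. Lines with missing IC50 for a
drug are excluded from that drug only, with a log message. For single-gene
stratification from variant-level calls, samples whose only events for the
gene are silent are excluded from both groups: they carry no non-silent
mutation yet are not mutation-free; unknown classification strings are
treated as non-silent and logged.

## Numerical and design notes

* All stochastic operations take an explicit seed or `numpy` Generator;
  sweeps derive child seeds (< 2^31) from a master Generator, and identical
  seeds reproduce results bit-for-bit.
* Matrix work orders nodes lexicographically; propagation is sparse
  matrix–vector iteration.
* Gene-symbol matching is exact and case-sensitive; dropped seed symbols are
  logged individually, and an all-dropped seed list is an error.
* Interaction-type strings are preserved through I/O but ignored by all
  computation; self-loop rows are dropped on read; duplicate and reversed
  rows merge with pathway-set union.
* Isolated nodes survive in memory but not through SIF round-trips (the
  format stores edges only); the synthetic generator never produces them.

## Known limitations

* The edge-universe enrichment treats edges as exchangeable, ignoring that
  subnetwork edges are induced by node selection; p-values are best read as
  rankings among represented pathways.
* Empirical p-values are calibrated against the degree-preserving null on
  unstructured networks; on strongly modular networks the null is
  intentionally conservative about community structure — that contrast is
  the signal, not a calibration defect.
* The MCS distance ignores edge agreement beyond the intersection and
  weighs all genes equally.
* No directed, weighted, or restart-probability propagation variants.
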