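# Methods

## The pooled pathway

Every pathway in the input collection is a directed graph whose nodes are
gene identifiers and whose edges are annotated interactions. The pooled
pathway is their union: a boolean adjacency `A` over the union `G` of all
pathway gene sets, with `A_ij = 1` iff some pathway annotates an
interaction from *i* to *j*. Conventions:

* Regulatory subtypes (activation, inhibition, expression, repression,
  phosphorylation, dephosphorylation, ubiquitination, indirect effect)
  map to a single directed edge. Binding/association maps to a
  bidirectional edge, i.e. both `A_ij` and `A_ji`. Dissociation, state
  change and missing interaction are ignored. This mapping is a
  reconstruction of common KGML practice and is fully overridable via a
  relation-map file; unknown subtypes follow a configurable default
  policy (ignore, with a warning).
* The diagonal is forced to zero: self-interactions never contribute to
  any score.
* `A` is boolean, not a count — an edge annotated by five pathways weighs
  the same as one annotated once.
* KGML `group` entries are expanded to their component genes with edges
  replicated to every component; compound-mediated (`PCrel`) and
  `maplink` relations are skipped, because the graph is gene-only. An
  entry naming several genes produces the full bipartite edge set between
  the endpoints' gene lists.
* Gene identifiers are used exactly as read (KEGG ids stay KEGG ids); any
  mapping to probe or symbol namespaces is the caller's responsibility.

**Chip restriction.** Before any scoring, rows and columns of genes not
present in the expression data are deleted — literally, with no
transitive closure, so an i→j→k chain with j unmeasured leaves i and k
unconnected. Pathways that lose all measured genes are kept with empty
membership and report enrichment p = 1, so the output always has one row
per input pathway.

## Evidence model

Direct evidence is a two-sided two-sample t-test per gene. Welch
(unequal-variance) is the default because it is the safer choice when
group variances differ; pooled-variance Student is available, as is a
plug-in per-gene p-value table for callers who prefer SAM, ANOVA, limma,
etc. Expression values are used as given — no log-transformation is
applied internally. Genes constant in both groups with equal means get
p = 1; a constant gene with shifted means gets the smallest representable
p-value. Zero p-values from plug-in tables are clamped to 1e-300 before
`−log10`.

The indirect score `SI_i = Σ_j A_ij (−log10 p_j^D)` sums over the
*out*-neighbours of *i*, following the printed orientation of the
formula; because pathway prose usually says "neighbours" without
direction, `direction_mode` can switch to in-neighbours or the union of
both. The permutation null shuffles the full `p^D` vector over all pooled
genes (including genes with no out-edges) N times with one seeded
generator per run; `p_i^I` counts shuffled scores **strictly** greater
than the observed one and is floored at 1/N. A `ties="ge"` option gives
the (count+1)/(N+1) convention instead. Genes with zero out-degree under
the chosen orientation have no indirect evidence and keep `p^C = p^D`.

Combining with Fisher's method assumes `p^D` and `p^I` are independent,
which holds formally because `SI_i` involves only the neighbours' direct
evidence, never gene *i*'s own. The pipeline logs the Pearson correlation
of `−log p^D` vs `−log p^I` as a diagnostic but does not switch to a
dependent-p-value combination automatically.

Default N = 2000 shuffles; values below 1000 warn (the p-value grid gets
coarse), below 100 are rejected.

## Enrichment

The universe is the set of measured pooled-pathway genes — not the whole
chip — because combined evidence is only defined there; this is
deliberate and documented rather than configurable away silently.
Significance is `p^C < 0.05`, strict. The per-pathway test is the
hypergeometric upper tail `P(X ≥ k)` including the observed count
(`phyper(k−1, ..., lower.tail=FALSE)` in R terms). FWER correction is
Bonferroni by default — the most conservative reading of "family-wise
error rate" — with Holm step-down available. Rows are sorted by
(`p_fwer`, `p_raw`, `pathway_id`) with a stable sort, so ranking is
deterministic under ties.

## Contextual association

`SC_αβ` is directional: only edges from α's genes into β's genes count,
so both ordered rows are reported (an optional symmetrization aggregates
them by max or sum). Genes shared by both pathways contribute every cross
edge they participate in, exactly as the double sum dictates. The
permutation null reuses one shared set of N weight-vector shuffles across
all pairs in a run, so (α, β) and (β, α) are scored against the same
draws. No multiple-testing correction is applied to `p_αβ` by default.
The static overlap test is hypergeometric on `|g^α ∩ g^β|` with the
pre-restriction pooled gene count as the default universe (the full
annotated complement, not the chip).

A degenerate case worth naming: a pair with no cross edges at all has
`SC = 0` in every shuffle too (topology is fixed), so its p-value sits at
the floor 1/N and is uninformative; the reported `n_cross_edges = 0`
flags it.

## False-positive calibration

Gene identifiers are permuted against the expression rows, preserving the
multiset of direct p-values and the topology while destroying their
alignment; the full pipeline is re-run per randomization and the fraction
of (randomization, pathway) outcomes with `p_FWER < 0.05` is reported
overall and per pathway.

## Synthetic data

The generator emulates the two structural facts the method relies on:
pathways sharing genes, and differential expression concentrated in
pathways. Pathways have a fixed size; consecutive pathways share exactly
`⌊overlap_fraction · size⌋` genes in a ring (wrapping when there are at
least three pathways; a "hub" pattern with one globally shared block is
available to stress highly connected genes). Directed edges are sampled
i.i.d. at `edge_density` over within-pathway ordered pairs, a fraction of
them relabelled as bidirectional binding edges. Expression is i.i.d.
normal with equal variance in both groups — matching the t-test's
assumptions so power is analytically checkable — and planted pathways
have a `de_fraction` subset of genes (default 0.5, a partial-deregulation
scenario) shifted by `d · noise_sd` in the condition group, each gene at
most once.

Defaults are a 12-pathway × 25-gene collection with overlap 0.2, edge
density 0.08, 10 samples per group, d = 1.5 — small enough to run in
seconds, large enough that the planted pathway is recoverable and
pathway-level type-I error is measurable over hundreds of
pathway-replicates. What passing tests on this generator do **not** show:
robustness to microarray-specific artefacts (probe saturation, batch
effects, correlated noise across genes) or to heavy-tailed expression
distributions; none of these are modelled.

The disjoint-pathway crosstalk fixture (two pathways with zero shared
genes, joined by five strong cross-edges annotated in a third, bridging
pathway) reproduces the scenario where contextual association detects a
relationship that any overlap-based method must miss: its `p_αβ` reaches
the 1/N floor while the static overlap p-value is exactly 1.

## Numerical choices

* Permutation p-values live on the 1/N grid and are floored at 1/N.
* Strict `>` counting, as a score tie should not count as evidence
  against the observed value.
* Fisher's combination is evaluated as the χ²(4 df) survival function;
  tests verify agreement with the closed form `q(1 − ln q)` to 1e-10
  relative.
* All randomness flows from one `numpy.random.default_rng(seed)` per
  operation; identical seeds give bitwise-identical outputs.
* The hypergeometric tail is validated exhaustively against direct
  combinatorial enumeration for every configuration with universe ≤ 25.

## Known limitations

* Boolean pooling discards interaction multiplicity and subtype identity;
  an inhibition and an activation edge are indistinguishable downstream.
* The permutation null treats all genes as exchangeable; genes with
  extreme chip-wide behaviour (e.g. expression-dependent variance) could
  make the null optimistic on real data.
* Enrichment and association p-values share the same direct evidence, so
  the two analyses are not independent of each other.
* Metabolic maps and compound nodes are out of scope; only gene–gene
  relations are modelled.
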