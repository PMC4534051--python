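# Methods

## The problem

Chemotherapy-induced peripheral neuropathy (CIPN) is a dose-limiting
toxicity of platinum compounds, taxanes and several other agents.  Genetic
association studies have implicated individual genes, but each study probes
a small candidate panel.  A network view asks a different question: given
the genes the literature has already implicated for an agent (the *focus
genes*), which other genes sit in densely interconnected neighborhoods
around them inside a global molecular-interaction knowledge base — and are
the resulting networks more focus-rich than chance would allow?

`cipn-netgrow` implements that pipeline end to end: a curated study corpus
(64 genetic-association studies of CIPN, 2003–2014) is packaged as
machine-readable fixtures; focus-gene sets per agent are derived from it;
networks are grown inside a knowledge base; each network receives an exact
hypergeometric enrichment p-value; hubs (≥ 15 connections) are reported;
and the degree distribution is checked against a power law on a log-log
plot.  Because curated commercial interactomes are proprietary, the
knowledge base is simulated by a generator with planted ground truth, so
recovery of the planted signal is measurable.

## Network-growth procedure

All connectivity is computed on the *undirected simple view* of the
knowledge base: multiple typed interactions between the same pair of
molecules collapse to a single adjacency and self-loops are dropped.  The
typed edges (activation, binding, inhibition, transcription, …, with a
direct/indirect flag) are retained for reporting but carry no weight in
the metrics, which are defined on "connections".

1. **Ranking.**  Focus genes are ranked by decreasing *triangular
   connectivity* — the number of connected neighbor pairs, i.e. triangles
   through the gene.  Focus genes with no connections at all are excluded
   from the analysis and reported, since a gene without relationships
   cannot participate in a network.  Ties break lexicographically on
   molecule id (here and everywhere below), which makes the whole analysis
   deterministic.
2. **Seed networks.**  The top-ranked uncovered focus gene seeds a
   network; the uncovered focus genes in its *neighborhood* (the gene plus
   genes exactly one connection away) join it.  This repeats until every
   non-excluded focus gene belongs to exactly one seed network.  Growth is
   a single one-hop step, not an iterated closure — iterated growth is the
   expansion phase's job.
3. **Merging.**  Seed networks are combined through bridging *non-focus*
   genes.  A bridge is a non-focus gene adjacent to (or, after an earlier
   merge, a member of) at least two networks.  The merge chosen at each
   step is the pair whose bridge has the highest *specific connectivity*
   with respect to the union of the two networks, subject to the size cap;
   greedy, re-evaluated after every merge.  Allowing an already-absorbed
   bridge to mediate a further merge lets several modules sharing a single
   hub collapse into one network.
4. **Expansion.**  Each network grows one gene at a time up to the size
   cap.  The admission score is specific connectivity,

       SC(g, V) = |N(g) ∩ V| / |N(g) ∪ V|,

   where N(g) is g's neighborhood (including g) and V the current network.
   This is a Jaccard-type score that rewards overlap with the network and
   penalises large neighborhoods through the union term, so no separate
   "fewest neighbors" criterion is needed.  Candidates are all knowledge-
   base molecules outside the network; expansion stops at the cap or when
   the best candidate scores 0.  Scores are compared as exact rationals
   (`fractions.Fraction`), so equal ratios tie exactly and the
   lexicographic tie-break is well defined; the greedy choice at each step
   does not depend on the cap, so admission sequences are prefix-monotone
   in `max_network_size`.

Focus-gene ownership is fixed in the seed phase: the focus sets of the
returned networks partition the non-excluded focus genes.  Expansion can
in principle pull a gene that is focus in *another* network into this one;
it then counts as an ordinary member here (and is not double-counted in
any `n_f`), keeping ownership disjoint.

## Scoring

A network of `n` genes with `n_f` focus genes is scored against the null
that it is a uniform random draw of `n` genes from the knowledge base
(`N` genes, `K` of them focus genes):

    p = Σ_{k=n_f}^{min(n,K)} C(K,k) C(N−K, n−k) / C(N,n),
    score = −log10 p.

The tail is computed with exact big-integer binomials and a single final
division — exact at any knowledge-base size used here, with no
approximation or underflow.  A network is significant at the conventional
threshold p < 10⁻⁵, i.e. score > 5.  No multiple-testing correction is
applied across networks (nominal threshold only, matching the convention
of the analysis this package reproduces).  By default all network members
count toward `n` and all molecules toward `N` (published pathway networks
include complexes and chemicals); a gene-only mode
(`count_nongene_nodes=False`) restricts both sides of the draw to
gene-kind molecules so that `n ≤ N` always holds.

Defaults follow the published settings: at most 140 genes per network
(large enough for one network to hold every focus set packaged here), at
most 25 networks per analysis, significance 10⁻⁵, hubs at ≥ 15
connections.

## Synthetic knowledge base

The generator emulates the structural features the algorithm exploits:

- **Scaffold:** preferential attachment (Barabási–Albert) with
  `n_background` genes and `m_attach` edges per new gene, giving the
  heavy-tailed, approximately power-law degree distribution expected of
  interactomes.  Defaults `n_background = 5000`, `m_attach = 2` describe a
  sparse desk-scale interactome; no statistics of the proprietary original
  are available, so these are the package's own calibration, exposed in
  config.
- **Planted modules:** each adds `module_size` genes with independent
  intra-module edges at `intra_density`, tied into the scaffold by
  `attach_edges` random edges (default 5 — a loosely anchored functional
  module), with `focus_count` members designated focus genes in the ground
  truth.  This realises the working hypothesis that biological function
  lives in locally dense neighborhoods.
- **Edge types:** relation sampled from the ten-type vocabulary
  (uniform weights by default), direct flag with probability 0.7.
- **Determinism:** one `numpy` generator seeded from the config drives
  everything, including the scaffold; identical configs give byte-identical
  sif-tsv output.

What it does **not** emulate: real interactome content, hub identity,
tissue specificity, literature-confidence weighting, or non-gene molecule
kinds (all generated molecules are genes).  Passing the recovery tests
therefore shows the algorithm finds planted dense modules under realistic
degree structure — not that it would reproduce any published network,
which would require the proprietary knowledge base.

The recovery benchmark uses a 3000-gene scaffold with one planted module
(30 genes, 20 focus, density 0.4) over 20 generator seeds, measuring the
fraction of planted focus genes captured by the top-scoring network and
that network's score.  These problem sizes run the whole benchmark in a
few seconds while leaving the module far above the scaffold's background
density.

## Literature fixtures

The study table (64 records: year, first author, ethnicity, cancer type,
sample size, phenotype, significant genes, agent group), the gene-by-agent
summary matrix with per-agent paper totals, the focus-gene sets (26
platinum, 19 taxane, 7 platinum/taxane) and the two hub tables (66
platinum entries, 6 platinum/taxane, all ≥ 15 connections) ship as TSV
fixtures with a SHA-256 manifest; loading verifies the checksums.  Gene
symbols are normalised to pathway-tool spelling (KCNN3 for SK3, CASP9 for
caspase 9, GJC3 for GJE1, SPIDR for KIAA0146-PRKD).  Agent-group
assignment of combination-therapy studies is curation frozen in the
fixture; `summarize_by_agent` is tested to reproduce the packaged matrix
cell-for-cell, so the records and the matrix are internally consistent by
construction.  Studies reporting no significant genes are retained: they
contribute to per-agent paper counts but to no matrix cells.  In the
platinum hub table the focus flag sits on ITGB3, the platinum network's
single focus gene, which is the reading consistent with the platinum
focus-gene list.

## Power-law diagnostic

`loglog_powerlaw_fit` performs ordinary least squares of log₁₀ freq(k) on
log₁₀ k over degrees k ≥ 1 with freq(k) ≥ 1 — the conventional raw
log-log plot — and reports slope, intercept and R².  Raw frequency fits
are noisy in the tail, so a CCDF mode is provided as the robust
alternative.  The fit deliberately emits no scale-free verdict: a
size-capped greedy grower cannot guarantee scale-freeness, and the
diagnostic only reports whether the points fall on a decaying line.  On
exact power-law input the slope is recovered to machine precision; on the
default scaffold the fit is strongly decaying (slope ≈ −2, R² ≈ 0.86).

## Numerical and design notes

- Hypergeometric tails: exact integer arithmetic rather than log-space
  summation; `scipy.stats.hypergeom` serves as an independent cross-check
  in the test suite, never as the implementation.
- Specific-connectivity comparisons use exact rationals; the public
  `specific_connectivity` returns a float.
- Whether "connections" should count parallel typed edges separately is
  unknowable from the published description; the simple-view collapse is
  the package's choice, surfaced as the `collapse_parallel_edges` config
  flag (only the collapsed mode is implemented).
- Seeds are not re-ranked after each seed network is consumed (the initial
  ranking is reused); the network-count cap applies after scoring.
- The pipeline derives stage seeds from the global seed by SHA-256 of
  `"{seed}:{stage}"`, so stages can be re-run in isolation and a manifest
  (config, version, seed, output checksums) makes runs reproducible
  byte-for-byte.

## Known limitations

- Node-for-node reproduction of the published CIPN networks is out of
  reach without the proprietary knowledge base; the packaged hub tables
  are fixtures, not recomputations.
- The merge phase is greedy pairwise; a globally optimal merge order is
  not attempted (nor defined by the source description).
- The degree-0 exclusion rule is the concrete reading of "excluded if less
  likely to have connections"; connected-but-peripheral focus genes are
  kept and may form singleton networks that score near 1.
- Maximum-likelihood power-law fitting with goodness-of-fit testing is
  deliberately out of scope; the package reproduces the log-log OLS check
  only.
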