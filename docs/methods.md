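# Methods

## Model and assumptions

The package treats a multi-compound preparation as a tripartite system:
compounds are linked to predicted protein targets (bipartite graph),
disease biology is represented by a high-confidence PPI neighbourhood
around seed genes (unipartite graph), and therapeutic hypotheses arise
from their intersection. All graphs are undirected and unweighted once
built: PPI confidence scores act solely as an inclusion filter, never as
edge lengths. This matches the convention of Cytoscape-style topological
analysis, whose normalized centralities the package reproduces.

Key assumptions:

- a compound–target prediction is either present or absent; prediction
  scores and directionality (activation/inhibition) are out of scope;
- the disease network is one shell deep — seeds plus first neighbors
  with all induced edges. Deeper shells would swamp the seed signal and
  are not part of the analysis;
- nodes without any surviving edge carry no information for hub or
  enrichment analysis and are dropped from every constructed network, so
  reported node counts always refer to endpoint-bearing nodes.

## Pipeline stages and parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| curation | dedup key | canonical SMILES, fallback case-folded name | structure identity beats naming variants |
| descriptors | panel | 8 physicochemical descriptors | computable from the structure alone; a user matrix can replace it |
| clustering | k | 5 | the customary cluster count for this 16-compound panel |
| clustering | init | k-means++, 10 restarts, 300 iters, tol 1e-6 | determinism under a fixed seed; restarts guard against poor local minima |
| PPI filter | cutoff, comparison | 0.7, strict (>) | literal reading of a "confidence higher than 0.7" extraction; `strict=False` gives ≥ |
| hub selection | thresholds | inclusive (≥), numeric or "mean" | mean-degree thresholds are standard in this workflow; "mean" resolves over role-filtered nodes |
| enrichment | test | hypergeometric upper tail | the one-sided Fisher test used by DAVID-family tools |
| enrichment | FDR | Benjamini–Hochberg, per category | "FDR" in enrichment tools is de facto BH; GO (BP/MF/CC) and pathway screens are separate analyses |
| enrichment | background | union of annotated genes | annotation-wide background, overridable by an explicit gene list |
| enrichment | cutoff | FDR < 0.01 | the screening threshold of the case study |
| enrichment | EASE | off | the deflated (k−1) variant exists behind a flag for DAVID comparability |

Threshold semantics worth pinning: hub comparisons are inclusive, so a
compound of exactly mean degree is a hub; the PPI filter is exclusive at
the boundary by default, so a score of exactly 0.7 is removed.

## Centrality conventions

Betweenness follows Brandes accumulation normalized by (n−1)(n−2)/2 for
undirected graphs; closeness is computed within each connected component
and scaled by the Wasserman–Faust factor (r−1)/(n−1), where r is the
component size. Both therefore live in [0, 1], which is the scale on
which published thresholds such as betweenness ≥ 0.01251 and closeness ≥
0.4547 are stated. The test suite checks both metrics against an
independent brute-force oracle (hand-written BFS distances plus the
pair-counting betweenness formula σ_st(v)/σ_st) on 200 seeded random
graphs of up to 50 nodes, to 1e−9.

## Synthetic data

`generate_inputs` draws the five pipeline inputs with exact,
user-controlled counts. Compound–target degrees come from a
Pareto-tailed weight vector (configuration-model style), reproducing the
empirical shape of compound promiscuity: one or two dominant compounds,
many selective ones. PPI confidence scores are Beta(8, 2), concentrating
mass above 0.7 as in a pre-filtered STRING export. The overlap between
putative targets and PPI nodes is exact (`n_common_targets`), which
makes intersection behaviour controllable down to the empty case.

`cki_fixture` is not a random draw: it is a constraint-satisfying
construction. Everything the case study prints is honoured exactly —
23 raw / 16 curated compounds; 326 bipartite edges over 180 targets with
compound degrees adenine 72, matrine 21, oxymatrine 21 and the 13 minor
compounds ≤ 20 summing to 212; a 97-seed, 188-node, 2019-edge PPI
network (mean degree 21.48); exactly 27 common targets giving a
39-node / 41-edge intersection whose target degrees are CHRNA3 6, DRD2 3,
PRKCA 3, CDK1/CDK2/CHRNA5/MMP1/MMP9 2 and nineteen singletons; an
annotation collection yielding exactly 22 significant pathways and 16 GO
terms (9 BP, 6 MF, 1 CC) at FDR < 0.01. The 20 hub edges named in the
docking table pin most of the intersected network; CHRNA5's two
compounds (never docked) are fixed to matrine and oxymatrine, and the
unnamed degree-1 targets and filler annotations are arbitrary but
deterministic. Construction is re-verified by internal assertions on
every call.

What the fixture does **not** emulate: real PPI topology. Its disease
network is a hub-and-circulant construction (TP53 wired to every node,
remaining edges on fixed circulant offsets), which reproduces the
printed node/edge counts and mean degree but concentrates betweenness on
TP53 — so the case study's "26 major PPI nodes" count is not a property
of the fixture and is not asserted anywhere. Likewise gene-set *content*
is synthetic: the pipeline reproduces the published significant-term
counts, not DAVID's 2018-era annotation database. Passing tests
demonstrate correctness of the algorithms under the published summary
statistics, not recovery of the original database retrievals.

## Numerical choices

- Hypergeometric tails are delegated to `scipy.stats.hypergeom.sf`,
  which evaluates the survival function stably; k = 0 returns exactly
  1.0 and results are clipped into (0, 1]. Exhaustive draw enumeration
  (all universes N ≤ 12) is the test oracle.
- BH q-values are delegated to statsmodels' `multipletests(method=
  "fdr_bh")`; a textbook step-up re-implementation is the test oracle on
  fixed vectors.
- Null calibration of the enrichment test uses term sizes
  (N = 1500, K = 400, n = 50) at which the discrete hypergeometric tail
  has an attainable level of 0.0498, immediately adjacent to the nominal
  0.05 — otherwise the discreteness of small-universe tests makes the
  empirical type-I rate unusable as a calibration check.
- K-means ties and label permutations are handled by scikit-learn; the
  package requires a standardized matrix and a fixed seed, making labels
  reproducible run-to-run. Constant descriptor columns are centred but
  not scaled.
- Hub ordering is degree-descending with lexicographic tie-break;
  "mean" thresholds are resolved on unrounded values (20.375, not
  20.38).

## Design choices on genuinely open points

- **Descriptor set and k.** The clustering stage of the original
  workflow names neither a descriptor panel, a distance, nor a selection
  rule for k = 5. The package fixes a small reproducible panel, the
  Euclidean metric on z-scores, and k = 5 as a config default — and
  accepts any precomputed matrix for users with a preferred panel.
- **PPI major-node thresholds.** Published values (21.48 / 0.01251 /
  0.4547) are consistent with "mean of each metric" for the degree but
  unverifiable for the other two; `HubCriteria` therefore accepts both
  explicit numbers and `"mean"` per metric.
- **Isolated seed genes.** Whether disease seeds absent from the
  filtered PPI should appear as isolates is unstated; the package drops
  them (consistent with all printed node counts) and records drops in
  the run summary.

## Problem sizes in the test suite

Unit and property tests run on graphs of ≤ 50 nodes (200 seeded draws
for the centrality oracle), exhaustive hypergeometric checks on
universes ≤ 12 genes, 1000-replicate null calibration, 100 random
input pairs for intersection properties, and two full pipeline runs for
determinism — the whole suite completes in well under a minute on one
CPU.

## Known limitations

- No live database clients; inputs are files or synthetic bundles.
- No molecular docking; the docking stage of the original workflow is an
  external web service and out of scope.
- Enrichment reproduces counts under synthetic annotations, not the
  identity of real enriched terms.
- Only unweighted, undirected centralities (degree, betweenness,
  closeness) are provided.
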