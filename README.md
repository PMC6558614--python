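# netpharm

Network pharmacology of multi-compound herbal preparations, built around
the Compound Kushen Injection (CKI) versus lung-cancer case study. CKI is
a two-herb preparation (kushen, baituling) whose many alkaloids each touch
many proteins; the package models that multi-compound / multi-target
situation as a set of linked networks instead of a single drug–receptor
pair. It is aimed at computational systems-biology and TCM-pharmacology
researchers who want the usual web-portal workflow (PubChem → target
prediction → STRING → Cytoscape → DAVID) as a reproducible, offline,
tested pipeline.

## What it computes

1. **Compound curation and clustering.** Structure-less and duplicated
   records are removed; the survivors are clustered with K-means (default
   k = 5) on an 8-descriptor physicochemical panel (MW, heavy atoms,
   rings, rotatable bonds, HBD, HBA, TPSA, fraction C sp3), z-scored.
2. **Four networks.**
   - compound–putative-target: bipartite graph of predicted associations;
   - disease PPI: seed genes plus first neighbors, induced over
     interactions with STRING-style combined score > 0.7;
   - compound–disease-target: the intersection — putative targets that
     also occur in the disease network, with their compound edges
     (compounds left without targets are dropped);
   - herb–compound–target–pathway: heterogeneous summary graph linking
     herbs to retained compounds, compounds to common targets, and
     targets to significantly enriched pathways.
3. **Centrality-based hub selection.** Degree, normalized betweenness
   (Brandes, scaled by (n−1)(n−2)/2) and Wasserman–Faust closeness, with
   inclusive thresholds that may be numbers or `"mean"`; hubs are the
   nodes meeting every stated threshold.
4. **Over-representation analysis.** For a query of n annotated genes,
   a term with K of N background genes and overlap k is scored with the
   hypergeometric upper tail P(X ≥ k) (one-sided Fisher), BH-FDR is
   applied within each annotation category, and terms with FDR < 0.01
   are reported with rich factor k/K and fold enrichment (k/n)/(K/N).
5. **Synthetic inputs.** A seeded generator emulates all five database
   retrievals (compound table, compound–target edges, disease seeds,
   scored PPI, GMT annotations), and `cki_fixture()` reconstructs a
   bundle constrained to the case study's printed statistics.

## Worked example

```python
from netpharm import (cki_fixture, curate_compounds, build_bipartite,
                      filter_ppi, expand_disease_network, intersect,
                      centralities, select_hubs, HubCriteria, enrich)

bundle = cki_fixture()
compounds = curate_compounds(bundle.compounds)      # 23 raw -> 16 curated
cpt = build_bipartite(compounds, bundle.ct_edges)   # 196 nodes, 326 edges

tab = centralities(cpt)
tab[tab.role == "compound"]["degree"].mean()        # 20.375  (prints as 20.38)
select_hubs(tab, HubCriteria(degree_min="mean", role_filter="compound"))
# ['adenine', 'matrine', 'oxymatrine']   (degrees 72, 21, 21)

ppi = filter_ppi(bundle.ppi_edges, 0.7)             # keeps score > 0.7
disease = expand_disease_network(bundle.disease_seeds, ppi)
2 * disease.n_edges / disease.n_nodes               # 21.48 mean degree (188 nodes, 2019 edges)

result = intersect(cpt, disease)                    # 39 nodes (12+27), 41 edges
itab = centralities(result.network)
select_hubs(itab, HubCriteria(degree_min="mean", role_filter="target"))
# ['CHRNA3', 'DRD2', 'PRKCA', 'CDK1', 'CDK2', 'CHRNA5', 'MMP1', 'MMP9']

rows = enrich(result.network.nodes_by_role("target"), bundle.gene_sets)
sum(r.category == "pathway" for r in rows)          # 22 pathways at FDR < 0.01
```

The mean compound degree 20.38 says a typical CKI compound is predicted
to touch ~20 proteins (multi-target behaviour); the three compounds above
that mean are the hub compounds, and the eight targets at or above the
intersected network's mean degree 1.52 are the candidate therapeutic
targets, CHRNA3 first.

The same analysis runs from the shell:

```bash
netpharm generate --fixture --outdir inputs
netpharm run --inputs inputs --outdir results-run --seed 1
```

which logs every resolved threshold (e.g. `compound hub thresholds:
{'degree': 20.375}`) and writes SIF/GraphML exports, centrality and
enrichment tables, and `report.json`. Individual stages are available as
`curate`, `cluster`, `build-net`, `ppi`, `intersect`, `topology`,
`enrich` and `assemble` subcommands operating on the persisted files.

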