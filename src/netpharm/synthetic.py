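"""Seeded generators for the five pipeline inputs, plus the deterministic
CKI / lung-cancer case-study fixture.

The pipeline consumes five tabular inputs that in the original study came
from interactive database queries (compound table, compound-target edges,
disease seed genes, scored PPI edges, annotation gene sets).  This module
fabricates all five offline:

* :func:`generate_inputs` draws a configurable random bundle — heavy-tailed
  compound degrees (a few promiscuous compounds, many selective ones),
  Beta-distributed PPI confidence scores, and a controllable overlap
  between the putative-target and PPI gene universes.
* :func:`cki_fixture` builds, with no randomness in its structure, a bundle
  constrained to the published statistics of the Compound Kushen Injection
  lung-cancer study: 16 curated compounds (from 23 raw entries), a
  196-node / 326-edge compound-putative-target network with compound
  degrees led by adenine (72), matrine (21) and oxymatrine (21); a
  188-node / 2019-edge high-confidence PPI network around 97 disease seed
  genes; exactly 27 shared target genes so that the intersected
  compound-disease network has 12 compounds, 27 targets and 41 edges with
  target hub degrees CHRNA3=6, DRD2=3, PRKCA=3 and CDK1/CDK2/CHRNA5/MMP1/
  MMP9=2; and an annotation collection yielding 22 significant pathways
  and 16 significant GO terms (9 BP, 6 MF, 1 CC) at FDR < 0.01.

Values the source study does not pin down (the degree-1 targets, the minor
compounds' degrees, filler gene membership) are fixed arbitrarily but
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from netpharm.model import (
    Compound,
    CompoundTargetEdge,
    GeneSet,
    PPIEdge,
    ValidationError,
)
from netpharm import io as npio


@dataclass
class InputBundle:
    """The five pipeline inputs, in memory."""

    compounds: list
    ct_edges: list
    disease_seeds: list
    ppi_edges: list
    gene_sets: list

    def write(self, outdir) -> dict:
        """Write the bundle to a directory in the standard dialects.

        Returns a mapping of input name to file path.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": outdir / "compounds.tsv",
            "ct_edges": outdir / "compound_targets.tsv",
            "disease_seeds": outdir / "disease_genes.txt",
            "ppi_edges": outdir / "ppi.tsv",
            "gene_sets": outdir / "annotations.gmt",
        }
        npio.write_compound_table(self.compounds, paths["compounds"])
        npio.write_ct_edges(self.ct_edges, paths["ct_edges"])
        npio.write_gene_list(self.disease_seeds, paths["disease_seeds"])
        npio.write_ppi_edges(self.ppi_edges, paths["ppi_edges"])
        npio.write_gene_sets(self.gene_sets, paths["gene_sets"])
        return {k: str(v) for k, v in paths.items()}


@dataclass
class SyntheticConfig:
    """Parameters of the random input generator.

    score_shape are the Beta-law parameters for PPI confidence scores;
    the default (8, 2) concentrates mass above the customary 0.7
    high-confidence cutoff, emulating a pre-filtered STRING extraction.
    annotation_coverage is the probability that any given putative target
    is annotated in at least one gene set.
    """

    n_compounds: int = 16
    n_putative_targets: int = 180
    n_ct_edges: int = 326
    n_disease_seeds: int = 97
    n_ppi_nodes: int = 188
    n_ppi_edges: int = 2019
    n_common_targets: int = 27
    n_terms: int = 60
    background_size: int = 900
    score_shape: tuple = (8.0, 2.0)
    annotation_coverage: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "n_compounds", "n_putative_targets", "n_ct_edges", "n_disease_seeds",
            "n_ppi_nodes", "n_ppi_edges", "n_terms", "background_size",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_common_targets < 0:
            raise ValidationError("n_common_targets must be non-negative")
        if self.n_ct_edges > self.n_compounds * self.n_putative_targets:
            raise ValidationError(
                "n_ct_edges exceeds the complete bipartite capacity "
                f"{self.n_compounds * self.n_putative_targets}"
            )
        if self.n_common_targets > min(self.n_putative_targets, self.n_ppi_nodes):
            raise ValidationError(
                "n_common_targets exceeds min(n_putative_targets, n_ppi_nodes)"
            )
        cap = self.n_ppi_nodes * (self.n_ppi_nodes - 1) // 2
        if self.n_ppi_edges > cap:
            raise ValidationError(f"n_ppi_edges exceeds simple-graph capacity {cap}")
        if self.n_disease_seeds > self.n_ppi_nodes:
            raise ValidationError("n_disease_seeds exceeds n_ppi_nodes")
        if not (0.0 <= self.annotation_coverage <= 1.0):
            raise ValidationError("annotation_coverage must be in [0, 1]")
        if min(self.score_shape) <= 0:
            raise ValidationError("score_shape parameters must be positive")


def _synthetic_smiles(i: int) -> str:
    """A distinct, trivially valid structure string per compound index."""
    return "C" * (1 + i // 2) + ("O" if i % 2 else "N")


def _heavy_tailed_quotas(rng, n_compounds, n_edges, cap, alpha=2.0):
    """Integer degree quotas summing to n_edges, each in [0, cap], drawn
    from a Pareto-tailed weight vector (configuration-model style)."""
    weights = (1.0 - rng.random(n_compounds)) ** (-1.0 / (alpha - 1.0))
    quotas = np.floor(n_edges * weights / weights.sum()).astype(int)
    quotas = np.minimum(quotas, cap)
    # distribute the remainder to compounds with spare capacity, largest
    # weight first (keeps the tail heavy)
    order = np.argsort(-weights)
    short = n_edges - int(quotas.sum())
    j = 0
    while short > 0:
        i = order[j % n_compounds]
        if quotas[i] < cap:
            quotas[i] += 1
            short -= 1
        j += 1
    return quotas


def generate_inputs(config: SyntheticConfig) -> InputBundle:
    """Draw a full input bundle; identical config (incl. seed) gives a
    bit-identical bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    compounds = [
        Compound(
            compound_id=f"C{i + 1:03d}",
            name=f"compound-{i + 1:03d}",
            smiles=_synthetic_smiles(i),
            herb="kushen" if i % 2 == 0 else "baituling",
        )
        for i in range(config.n_compounds)
    ]
    targets = [f"T{i + 1:04d}" for i in range(config.n_putative_targets)]

    # compound-target edges: heavy-tailed compound degrees, every target
    # covered first when the edge budget allows it
    quotas = _heavy_tailed_quotas(
        rng, config.n_compounds, config.n_ct_edges, config.n_putative_targets
    )
    linked = [set() for _ in range(config.n_compounds)]
    remaining = quotas.copy()
    if config.n_ct_edges >= config.n_putative_targets:
        order = np.argsort(-quotas)
        j = 0
        for t_idx in range(config.n_putative_targets):
            while True:
                c = int(order[j % config.n_compounds])
                j += 1
                if remaining[c] > 0:
                    linked[c].add(t_idx)
                    remaining[c] -= 1
                    break
    for c in range(config.n_compounds):
        if remaining[c] > 0:
            pool = np.setdiff1d(
                np.arange(config.n_putative_targets), np.fromiter(linked[c], int, len(linked[c]))
            )
            picks = rng.choice(pool, size=int(remaining[c]), replace=False)
            linked[c].update(int(p) for p in picks)
    ct_edges = [
        CompoundTargetEdge(compounds[c].compound_id, targets[t], "synthetic")
        for c in range(config.n_compounds)
        for t in sorted(linked[c])
    ]

    # PPI node universe: shared target symbols + disease-only genes
    common_idx = rng.choice(
        config.n_putative_targets, size=config.n_common_targets, replace=False
    )
    common = [targets[i] for i in sorted(common_idx)]
    disease_only = [
        f"D{i + 1:04d}" for i in range(config.n_ppi_nodes - config.n_common_targets)
    ]
    ppi_nodes = common + disease_only
    seeds = ppi_nodes[: config.n_disease_seeds]

    g = nx.gnm_random_graph(
        config.n_ppi_nodes, config.n_ppi_edges, seed=int(rng.integers(2**31))
    )
    scores = rng.beta(*config.score_shape, size=config.n_ppi_edges)
    ppi_edges = [
        PPIEdge(ppi_nodes[u], ppi_nodes[v], float(s))
        for (u, v), s in zip(sorted(g.edges()), scores)
    ]

    # annotation gene sets over a background of targets, PPI genes, fillers
    core = sorted(set(targets) | set(ppi_nodes))
    if config.background_size < len(core):
        raise ValidationError(
            f"background_size {config.background_size} smaller than the "
            f"{len(core)} target/PPI genes"
        )
    fillers = [f"BG{i + 1:05d}" for i in range(config.background_size - len(core))]
    universe = core + fillers
    members = [set() for _ in range(config.n_terms)]
    for t in targets:
        if rng.random() < config.annotation_coverage:
            members[int(rng.integers(config.n_terms))].add(t)
    categories = ["BP", "MF", "CC", "pathway"]
    gene_sets = []
    for i in range(config.n_terms):
        size = int(rng.integers(10, 50))
        extra = rng.choice(len(universe), size=size, replace=False)
        members[i].update(universe[j] for j in extra)
        gene_sets.append(
            GeneSet(
                term_id=f"TERM{i + 1:04d}",
                term_name=f"synthetic term {i + 1}",
                category=categories[i % 4],
                genes=frozenset(members[i]),
            )
        )
    return InputBundle(compounds, ct_edges, seeds, ppi_edges, gene_sets)


# =====================================================================
# The CKI / lung-cancer case-study fixture
# =====================================================================

_FIXTURE_SEED = 12345  # only used for PPI confidence-score noise

# The 16 curated compounds: (name, smiles, herb).  Structures are valid
# canonical SMILES; the matrine-family stereoisomers are distinguished by
# stereo annotations.  Macrozamin is the single baituling constituent.
_COMPOUNDS = [
    ("adenine", "Nc1ncnc2[nH]cnc12", "kushen"),
    ("matrine", "O=C1CCC[C@@H]2[C@H]3CCCN4CCC[C@H](CN12)[C@@H]34", "kushen"),
    ("oxymatrine", "O=C1CCCC2C3CCC[N+]4([O-])CCCC(CN12)C34", "kushen"),
    ("macrozamin", "CN=[N+]([O-])COC1OC(COC2OCC(O)C(O)C2O)C(O)C(O)C1O", "baituling"),
    ("baptifoline", "O=c1cccc2n1CC1CC(O)CC2C1", "kushen"),
    ("n-methylcytisine", "CN1CC2CC(C1)c1cccc(=O)n1C2", "kushen"),
    ("isomatrine", "O=C1CCC[C@H]2[C@@H]3CCCN4CCC[C@@H](CN12)[C@H]34", "kushen"),
    ("sophoridine", "O=C1CCC[C@H]2[C@H]3CCCN4CCC[C@H](CN12)[C@@H]34", "kushen"),
    ("lamprolobine", "NC(=O)CN1CCCC2(CCCC(=O)N2)C1", "kushen"),
    ("sophocarpine", "O=C1C=CCC2C3CCCN4CCCC(CN12)C34", "kushen"),
    ("9a-hydroxymatrine", "O=C1CCCC2C3CCCN4CC(O)CC(CN12)C34", "kushen"),
    ("sophoranol", "OC1CCC2N(C1)CC1CCCN3CCCC(C13)C2=O", "kushen"),
    ("sophoramine", "O=C1C=CCC2C3C=CCN4CCCC(CN12)C34", "kushen"),
    ("cytisine", "O=c1cccc2n1CC1CNCC2C1", "kushen"),
    ("trifolirhizin", "O=C1CC(c2ccc3OCOc3c2)Oc2ccccc21", "kushen"),
    ("kurarinol", "CC(C)=CCC(O)c1cc(O)c2C(=O)CC(c3ccc(O)cc3O)Oc2c1", "kushen"),
]

# Seven raw entries removed by curation: three duplicates (case-variant or
# alias names, identical structures) and four structure-less records.
_RAW_EXTRA = [
    ("Matrine", "O=C1CCC[C@@H]2[C@H]3CCCN4CCC[C@H](CN12)[C@@H]34", "kushen"),
    ("Oxymatrine", "O=C1CCCC2C3CCC[N+]4([O-])CCCC(CN12)C34", "kushen"),
    ("sophocarpidine", "O=C1C=CCC2C3CCCN4CCCC(CN12)C34", "kushen"),
    ("kushenol A", None, "kushen"),
    ("kuraridinol", None, "kushen"),
    ("sophoflavescenol", None, "kushen"),
    ("norkurarinol", None, "kushen"),
]

# Total putative-network degree per compound.  adenine/matrine/oxymatrine
# carry the published 72/21/21; the other 13 are fixed so that each stays
# <= 20 and the 13 sum to 212 (total 326 edges).
_PUTATIVE_DEGREE = {
    "adenine": 72, "matrine": 21, "oxymatrine": 21,
    "macrozamin": 20, "baptifoline": 20, "n-methylcytisine": 20,
    "isomatrine": 20, "sophoridine": 18, "lamprolobine": 16,
    "sophocarpine": 16, "9a-hydroxymatrine": 16, "sophoranol": 16,
    "sophoramine": 14, "cytisine": 12, "trifolirhizin": 12, "kurarinol": 12,
}

# Intersected-network edges whose compounds the study names per hub target
# (docking Table pairs for seven hubs; CHRNA5, never docked, is assigned
# the two principal alkaloids).
_HUB_EDGES = {
    "CHRNA3": ["isomatrine", "baptifoline", "matrine", "sophoridine",
               "lamprolobine", "n-methylcytisine"],
    "DRD2": ["baptifoline", "sophocarpine", "n-methylcytisine"],
    "PRKCA": ["9a-hydroxymatrine", "sophoranol", "adenine"],
    "CDK1": ["macrozamin", "adenine"],
    "CDK2": ["macrozamin", "adenine"],
    "CHRNA5": ["matrine", "oxymatrine"],
    "MMP1": ["adenine", "oxymatrine"],
    "MMP9": ["adenine", "matrine"],
}

# The 19 degree-1 common targets and their single compound.
_DEGREE1_EDGES = {
    "CCND1": "matrine",
    "TLR2": "oxymatrine",
    "TLR4": "oxymatrine",
    "TOP2A": "macrozamin",
    "ESR1": "baptifoline",
    "CHRNB4": "n-methylcytisine",
    "EGFR": "adenine", "KRAS": "adenine", "MET": "adenine", "ALK": "adenine",
    "BRAF": "adenine", "PIK3CA": "adenine", "AKT1": "adenine",
    "STAT3": "adenine", "VEGFA": "adenine", "SRC": "adenine",
    "ERBB2": "adenine", "FGFR1": "adenine", "MTOR": "adenine",
}

# The 22 significant pathways of the case study (order as printed).
_PATHWAYS = [
    ("hsa05205", "Proteoglycans in cancer"),
    ("hsa05223", "Non-small cell lung cancer"),
    ("hsa05200", "Pathways in cancer"),
    ("hsa05214", "Glioma"),
    ("hsa05219", "Bladder cancer"),
    ("hsa05215", "Prostate cancer"),
    ("hsa05212", "Pancreatic cancer"),
    ("hsa05218", "Melanoma"),
    ("hsa05213", "Endometrial cancer"),
    ("hsa05220", "Chronic myeloid leukemia"),
    ("hsa05222", "Small cell lung cancer"),
    ("hsa04068", "FoxO signaling pathway"),
    ("hsa04510", "Focal adhesion"),
    ("hsa04914", "Progesterone-mediated oocyte maturation"),
    ("hsa04915", "Estrogen signaling pathway"),
    ("hsa04115", "p53 signaling pathway"),
    ("hsa04015", "Rap1 signaling pathway"),
    ("hsa05161", "Hepatitis B"),
    ("hsa04151", "PI3K-Akt signaling pathway"),
    ("hsa05162", "Measles"),
    ("hsa04012", "ErbB signaling pathway"),
    ("hsa04066", "HIF-1 signaling pathway"),
]

# The 16 significant GO terms (9 BP, 6 MF, 1 CC).
_GO_TERMS = [
    ("GO:0006468", "BP", "protein phosphorylation"),
    ("GO:0070374", "BP", "positive regulation of ERK1 and ERK2 cascade"),
    ("GO:0000082", "BP", "G1/S transition of mitotic cell cycle"),
    ("GO:0010628", "BP", "positive regulation of gene expression"),
    ("GO:0038128", "BP", "ERBB2 signaling pathway"),
    ("GO:0048015", "BP", "phosphatidylinositol-mediated signaling"),
    ("GO:0001934", "BP", "positive regulation of protein phosphorylation"),
    ("GO:0046777", "BP", "protein autophosphorylation"),
    ("GO:0014066", "BP", "regulation of phosphatidylinositol 3-kinase signaling"),
    ("GO:0004672", "MF", "protein kinase activity"),
    ("GO:0004674", "MF", "protein serine/threonine kinase activity"),
    ("GO:0005524", "MF", "ATP binding"),
    ("GO:0004693", "MF", "cyclin-dependent protein serine/threonine kinase activity"),
    ("GO:0016301", "MF", "kinase activity"),
    ("GO:0030332", "MF", "cyclin binding"),
    ("GO:0000307", "CC", "cyclin-dependent protein kinase holoenzyme complex"),
]

# Non-significant decoy terms (one query gene each, large filler load).
_DECOYS = [
    ("hsa00010", "pathway", "Glycolysis / Gluconeogenesis"),
    ("hsa00190", "pathway", "Oxidative phosphorylation"),
    ("hsa00230", "pathway", "Purine metabolism"),
    ("hsa00240", "pathway", "Pyrimidine metabolism"),
    ("hsa00500", "pathway", "Starch and sucrose metabolism"),
    ("hsa00620", "pathway", "Pyruvate metabolism"),
    ("hsa03010", "pathway", "Ribosome"),
    ("hsa03020", "pathway", "RNA polymerase"),
    ("hsa03030", "pathway", "DNA replication"),
    ("hsa03050", "pathway", "Proteasome"),
    ("hsa03060", "pathway", "Protein export"),
    ("hsa04122", "pathway", "Sulfur relay system"),
    ("hsa00983", "pathway", "Drug metabolism - other enzymes"),
    ("hsa00982", "pathway", "Drug metabolism - cytochrome P450"),
    ("hsa04744", "pathway", "Phototransduction"),
    ("GO:0006412", "BP", "translation"),
    ("GO:0006397", "BP", "mRNA processing"),
    ("GO:0006281", "BP", "DNA repair"),
    ("GO:0006099", "BP", "tricarboxylic acid cycle"),
    ("GO:0015031", "BP", "protein transport"),
    ("GO:0006457", "BP", "protein folding"),
    ("GO:0006091", "BP", "generation of precursor metabolites and energy"),
    ("GO:0048870", "BP", "cell motility"),
    ("GO:0003735", "MF", "structural constituent of ribosome"),
    ("GO:0005198", "MF", "structural molecule activity"),
    ("GO:0016787", "MF", "hydrolase activity"),
    ("GO:0004386", "MF", "helicase activity"),
    ("GO:0003824", "MF", "catalytic activity"),
    ("GO:0008233", "MF", "peptidase activity"),
    ("GO:0005840", "CC", "ribosome"),
    ("GO:0005739", "CC", "mitochondrion"),
    ("GO:0005783", "CC", "endoplasmic reticulum"),
    ("GO:0005794", "CC", "Golgi apparatus"),
    ("GO:0016020", "CC", "membrane"),
]

_N_FILLER_GENES = 873  # background = 27 common targets + fillers = 900


def _fixture_common_targets() -> list:
    """The 27 common targets: 8 hubs + 19 degree-1 genes, hub-first order."""
    return list(_HUB_EDGES) + list(_DEGREE1_EDGES)


def _fixture_ct_edges() -> list:
    """The 326 compound-putative-target edges.

    The 41 edges incident to the 27 common targets are pinned explicitly;
    the remaining 285 edges are distributed over 153 non-common putative
    targets by a deterministic cyclic walk, with the matrine/oxymatrine
    edges to CHRNA4 and CHRNB2 (named in the study) placed first.
    """
    edges = set()
    for target, comps in _HUB_EDGES.items():
        for c in comps:
            edges.add((c, target))
    for target, c in _DEGREE1_EDGES.items():
        edges.add((c, target))
    common_deg = {}
    for c, _t in edges:
        common_deg[c] = common_deg.get(c, 0) + 1

    noncommon = ["CHRNA4", "CHRNB2"] + [f"PT{i:03d}" for i in range(1, 152)]
    special = {"matrine": ["CHRNA4", "CHRNB2"], "oxymatrine": ["CHRNA4", "CHRNB2"]}
    ptr = 0
    for name, _smiles, _herb in _COMPOUNDS:
        quota = _PUTATIVE_DEGREE[name] - common_deg.get(name, 0)
        for t in special.get(name, []):
            edges.add((name, t))
            quota -= 1
        while quota > 0:
            t = noncommon[ptr % len(noncommon)]
            ptr += 1
            if (name, t) not in edges:
                edges.add((name, t))
                quota -= 1
    return [CompoundTargetEdge(c, t, "fixture") for c, t in sorted(edges)]


def _fixture_ppi() -> tuple:
    """The disease PPI: 97 seed genes, 188 nodes, 2019 edges, scores > 0.7.

    TP53 is wired as the central hub (adjacent to every other node), which
    both reflects its role in the study's PPI network and guarantees that
    the one-shell expansion around the seeds recovers all 188 nodes.
    Remaining edges come from fixed circulant offsets.
    """
    common = _fixture_common_targets()
    seeds = ["TP53", "PCNA"] + common + [f"LC{i:03d}" for i in range(1, 69)]
    assert len(seeds) == 97
    nodes = seeds + [f"NB{i:03d}" for i in range(1, 92)]
    assert len(nodes) == 188

    pairs = [(0, j) for j in range(1, 188)]  # TP53 star
    have = set(pairs)
    gap = 2
    while len(pairs) < 2019:
        for i in range(188):
            j = (i + gap) % 188
            key = (min(i, j), max(i, j))
            if i == j or key in have:
                continue
            have.add(key)
            pairs.append(key)
            if len(pairs) == 2019:
                break
        gap += 1

    rng = np.random.default_rng(_FIXTURE_SEED)
    scores = rng.uniform(0.701, 0.999, size=len(pairs))
    edges = [
        PPIEdge(nodes[i], nodes[j], round(float(s), 3))
        for (i, j), s in zip(pairs, scores)
    ]
    return seeds, edges


def _fixture_gene_sets() -> list:
    """Annotation collection: 22 enriched pathways, 16 enriched GO terms,
    34 decoy terms, over a 900-gene background (27 targets + 873 fillers).

    Each enriched term holds k targets (k cycles over a fixed schedule,
    larger for the broad cancer/PI3K-Akt pathways) plus a modest filler
    load; decoys hold one target and 40 fillers, which keeps them far from
    the FDR < 0.01 cut.
    """
    query = _fixture_common_targets()
    fillers = [f"BG{i + 1:05d}" for i in range(_N_FILLER_GENES)]
    # k per significant pathway, aligned with _PATHWAYS order
    k_pathway = [6, 5, 8, 5, 5, 5, 5, 5, 5, 5, 5, 6, 5, 5, 5, 5, 6, 5, 7, 5, 5, 5]
    k_go = [7, 5, 5, 6, 5, 5, 5, 5, 5, 6, 5, 8, 5, 6, 5, 4]

    q_ptr = 0
    f_ptr = 0

    def take_query(k):
        nonlocal q_ptr
        out = [query[(q_ptr + j) % len(query)] for j in range(k)]
        q_ptr += k
        return out

    def take_fillers(f):
        nonlocal f_ptr
        out = [fillers[(f_ptr + j) % len(fillers)] for j in range(f)]
        f_ptr += f
        return out

    sets = []
    for i, (term_id, term_name) in enumerate(_PATHWAYS):
        genes = take_query(k_pathway[i]) + take_fillers(10 + (3 * i) % 11)
        sets.append(GeneSet(term_id, term_name, "pathway", frozenset(genes)))
    for i, (term_id, category, term_name) in enumerate(_GO_TERMS):
        genes = take_query(k_go[i]) + take_fillers(10 + (3 * i) % 11)
        sets.append(GeneSet(term_id, term_name, category, frozenset(genes)))
    for i, (term_id, category, term_name) in enumerate(_DECOYS):
        genes = take_query(1) + take_fillers(40)
        sets.append(GeneSet(term_id, term_name, category, frozenset(genes)))
    return sets


def _verify_fixture(bundle: InputBundle) -> None:
    """Internal consistency assertions for the constructed fixture."""
    from netpharm.chem import curate_compounds
    from netpharm.networks import build_bipartite, filter_ppi, expand_disease_network, intersect

    curated = curate_compounds(bundle.compounds)
    assert len(bundle.compounds) == 23 and len(curated) == 16
    bip = build_bipartite(curated, bundle.ct_edges)
    assert bip.n_nodes == 196 and bip.n_edges == 326
    deg = dict(bip.graph.degree())
    assert deg["adenine"] == 72 and deg["matrine"] == 21 and deg["oxymatrine"] == 21
    kept = filter_ppi(bundle.ppi_edges, 0.7, strict=True)
    disease = expand_disease_network(bundle.disease_seeds, kept)
    assert disease.n_nodes == 188 and disease.n_edges == 2019
    result = intersect(bip, disease)
    net = result.network
    assert len(result.common_targets) == 27
    assert net.n_nodes == 39 and net.n_edges == 41
    tdeg = sorted(
        (dict(net.graph.degree())[t] for t in net.nodes_by_role("target")),
        reverse=True,
    )
    assert tdeg[:8] == [6, 3, 3, 2, 2, 2, 2, 2] and set(tdeg[8:]) == {1}


def cki_fixture(verify: bool = True) -> InputBundle:
    """Build the deterministic CKI / lung-cancer case-study bundle.

    The construction is verified by internal assertions (disable with
    ``verify=False`` when the downstream modules are under test).
    """
    compounds = [
        Compound(compound_id=name, name=name, smiles=smiles, herb=herb)
        for name, smiles, herb in _COMPOUNDS + _RAW_EXTRA
    ]
    ct_edges = _fixture_ct_edges()
    seeds, ppi_edges = _fixture_ppi()
    gene_sets = _fixture_gene_sets()
    bundle = InputBundle(compounds, ct_edges, seeds, ppi_edges, gene_sets)
    if verify:
        _verify_fixture(bundle)
    return bundle
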