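"""Seeded random fixtures: trees, Brownian traits and genome records.

These generators back the test harness: random rooted trees with branch
lengths, traits simulated under Brownian motion (optionally with a Pagel
lambda rescaling), and genome-record collections with planted curation
defects. Everything is driven by numpy Generators so fixtures are
reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np

from .curation import GenomeRecord, SpeciesReference
from .trait import TraitTree
from .signal import brownian_covariance

__all__ = ["random_tree", "simulate_bm_traits", "random_genome_records"]


def random_tree(n_tips: int, seed: Optional[int] = None,
                min_bl: float = 0.1, max_bl: float = 2.0) -> TraitTree:
    """Random rooted binary tree built by repeated random joins, with
    uniform branch lengths in [min_bl, max_bl] and tips t0..t{n-1}."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        leaf = dendropy.Node()
        leaf.taxon = ns.new_taxon(f"t{i}")
        leaf.edge.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(min_bl, max_bl))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns)
    root = nodes[0]
    root.edge.length = None
    tree.seed_node = root
    return TraitTree(tree)


def simulate_bm_traits(tree: TraitTree, seed: Optional[int] = None,
                       root_state: float = 5.0, rate: float = 1.0,
                       lam: float = 1.0) -> Dict[str, float]:
    """Simulate tip traits under Brownian motion on the tree.

    Draws one multivariate-normal sample with covariance rate * V(lam),
    where V(lam) is the Brownian tip covariance with off-diagonal entries
    multiplied by ``lam``. Returns a map tip label -> value.
    """
    C, labels = brownian_covariance(tree)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(rate * V + 1e-12 * np.eye(len(labels)))
    x = root_state + L @ rng.standard_normal(len(labels))
    return dict(zip(labels, x))


def random_genome_records(n_clean: int, n_resolvable: int, n_unresolvable: int,
                          seed: Optional[int] = None
                          ) -> Tuple[List[GenomeRecord], Dict[str, SpeciesReference]]:
    """Genome-record collection with planted curation outcomes.

    Clean records agree across catalog and both predictors; resolvable ones
    carry a zeroed or inflated catalog value but predictors consistent with
    their species reference; unresolvable ones have all sources mutually
    inconsistent and no reference entry. Returns (records, references).
    """
    rng = np.random.default_rng(seed)
    records: List[GenomeRecord] = []
    refs: Dict[str, SpeciesReference] = {}
    k = 0

    def new_id():
        nonlocal k
        k += 1
        return f"g{k:04d}"

    for _ in range(n_clean):
        gcn = int(rng.integers(1, 13))
        sp = f"Clean_sp{k}"
        refs[sp] = SpeciesReference(sp, float(gcn), int(rng.integers(1, 6)))
        records.append(GenomeRecord(new_id(), sp, gcn, gcn, gcn,
                                    gene_lengths=(1500,) * gcn,
                                    avg_contig_kbp=500.0, scaffold_kbp=3000.0))
    for _ in range(n_resolvable):
        gcn = int(rng.integers(2, 13))
        sp = f"Fixable_sp{k}"
        refs[sp] = SpeciesReference(sp, float(gcn), int(rng.integers(2, 6)))
        records.append(GenomeRecord(new_id(), sp, 0, gcn, gcn,
                                    gene_lengths=(1500,) * gcn,
                                    catalog_5s_gcn=gcn, catalog_23s_gcn=gcn,
                                    avg_contig_kbp=500.0, scaffold_kbp=3000.0))
    for _ in range(n_unresolvable):
        sp = f"Broken_sp{k}"
        records.append(GenomeRecord(new_id(), sp, 0, 3, 7,
                                    gene_lengths=(800, 900),
                                    avg_contig_kbp=150.0, scaffold_kbp=150.0))
    return records, refs
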