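"""GCN estimation on a reference phylogeny by independent contrasts.

Given a rooted tree in which a subset of tips carries an empirical 16S GCN
(from curated sequenced genomes), this module estimates the trait for every
internal node with Felsenstein's phylogenetically independent contrasts
(PIC) recursion, predicts the trait of every trait-less tip by rerooting the
tree at the tip's attachment point, and aggregates node estimates into
per-taxon values. The final product is a :class:`GcnLookup` mapping taxon
identifiers and taxonomic strings to GCN, which the profile-correction
engine consumes.

The PIC recursion combines daughter values by inverse-branch-length
weighting: for a node k with daughters carrying values x_i on (adjusted)
branch lengths v_i,

    x_k = sum(x_i / v_i) / sum(1 / v_i)

and the branch below k is lengthened by 1 / sum(1/v_i) to account for the
uncertainty of x_k. At the root this yields the maximum-likelihood root
state under Brownian motion, and — because Brownian motion is reversible —
rerooting at an unsampled tip's attachment node turns the same recursion
into the best linear prediction of that tip's value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TraitTree",
    "TipTrait",
    "TraitEstimate",
    "GcnLookup",
    "map_genomes_to_tips",
    "pic_ancestral_states",
    "predict_unknown_tips",
    "aggregate_taxon_gcn",
    "build_lookup",
]

#: Zero-length branches are replaced by this fraction of the mean branch
#: length so inverse-length weights stay finite.
ZERO_LENGTH_EPS_FACTOR = 1e-6


class EstimationError(ValueError):
    """Raised when no empirical trait values are available for estimation."""


@dataclass(frozen=True)
class TipTrait:
    """An empirical tip value: the mean GCN of the genomes mapped to a tip
    and the number of genomes averaged (used downstream as a weight)."""

    gcn: float
    weight: int = 1

    def __post_init__(self):
        if self.gcn <= 0:
            raise ValueError("gcn must be positive")
        if self.weight < 1:
            raise ValueError("weight must be >= 1")


@dataclass(frozen=True)
class TraitEstimate:
    """A GCN estimate for a node or tip.

    ``weight`` counts the empirical tip values contributing to the estimate;
    ``empirical`` marks values observed directly (genome averages) rather
    than reconstructed.
    """

    gcn: float
    weight: int
    empirical: bool


class TraitTree:
    """A rooted phylogeny with branch lengths and optional node taxon labels.

    Thin wrapper over a :class:`dendropy.Tree`. Tip labels must be unique;
    internal-node labels, when present, are interpreted as taxon labels
    (several nodes may share one taxon).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")

    @classmethod
    def from_newick(cls, source: str) -> "TraitTree":
        """Parse a Newick string or file path (quoted labels supported)."""
        if "(" in source:
            tree = dendropy.Tree.get(data=source, schema="newick",
                                     suppress_internal_node_taxa=True,
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=source, schema="newick",
                                     suppress_internal_node_taxa=True,
                                     preserve_underscores=True)
        return cls(tree)

    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def taxon_labels(self) -> Dict[str, str]:
        """Map node identifier -> taxon label for labelled internal nodes."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf() and node.label:
                out[node.label] = node.label
        return out

    def clone(self) -> dendropy.Tree:
        return self.tree.clone(depth=1)


def map_genomes_to_tips(assignments: Iterable[Tuple[str, str, float]]) -> Dict[str, TipTrait]:
    """Average the GCN of all genomes assigned to each tip.

    ``assignments`` is an iterable of (genome_id, tip_label, gcn). Returns a
    map tip label -> :class:`TipTrait` whose weight is the number of genomes
    averaged. An empty assignment list yields an empty map.
    """
    values: Dict[str, list] = {}
    for genome_id, tip_label, gcn in assignments:
        if gcn <= 0:
            raise ValueError(f"gcn must be positive (genome {genome_id})")
        values.setdefault(tip_label, []).append(float(gcn))
    return {tip: TipTrait(float(np.mean(v)), len(v)) for tip, v in values.items()}


def _as_tip_traits(traits: Mapping) -> Dict[str, TipTrait]:
    out = {}
    for k, v in traits.items():
        out[k] = v if isinstance(v, TipTrait) else TipTrait(float(v))
    return out


def _branch_eps(tree: dendropy.Tree) -> float:
    lengths = [e.length for e in tree.preorder_edge_iter()
               if e.length is not None and e.length > 0]
    mean = float(np.mean(lengths)) if lengths else 1.0
    return ZERO_LENGTH_EPS_FACTOR * mean


def _edge_length(node: dendropy.Node, eps: float) -> float:
    l = node.edge.length
    return eps if (l is None or l <= 0) else float(l)


def _pic_postorder(tree: dendropy.Tree, traits: Mapping[str, TipTrait]):
    """Run the PIC recursion; annotates each node with (value, adjusted
    branch length, weight). Returns the per-node dict."""
    eps = _branch_eps(tree)
    state = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in traits:
                raise EstimationError(f"tip {label!r} lacks a trait value")
            t = traits[label]
            state[node] = (t.gcn, _edge_length(node, eps), t.weight)
        else:
            children = node.child_nodes()
            xs = np.array([state[c][0] for c in children])
            vs = np.array([state[c][1] for c in children])
            w = sum(state[c][2] for c in children)
            inv = np.sum(1.0 / vs)
            x = float(np.sum(xs / vs) / inv)
            v = _edge_length(node, eps) + 1.0 / inv
            state[node] = (x, v, w)
    return state


def pic_ancestral_states(tree: TraitTree, traits: Mapping) -> Dict:
    """Estimate the trait of every internal node by the PIC recursion.

    Every tip must carry a trait (prune first otherwise). Returns a map
    from node key to :class:`TraitEstimate`; internal nodes are keyed by
    their label when present, otherwise by a stable positional key
    ``node<i>`` in preorder. Tips are included as empirical entries.
    """
    traits = _as_tip_traits(traits)
    work = tree.clone()
    state = _pic_postorder(work, traits)
    out: Dict[str, TraitEstimate] = {}
    i = 0
    for node in work.preorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            t = traits[label]
            out[label] = TraitEstimate(t.gcn, t.weight, True)
        else:
            key = node.label if node.label else f"node{i}"
            x, _, w = state[node]
            out[key] = TraitEstimate(x, w, False)
        i += not node.is_leaf()
    return out


def _root_estimate(tree: dendropy.Tree, traits: Mapping[str, TipTrait]) -> Tuple[float, int]:
    state = _pic_postorder(tree, traits)
    x, _, w = state[tree.seed_node]
    return x, w


def predict_unknown_tips(tree: TraitTree, traits: Mapping) -> Dict[str, TraitEstimate]:
    """Predict the trait of every tip lacking an empirical value.

    For each query tip: all other trait-less tips are pruned, the pruned
    tree is rerooted at the query's attachment node, and the PIC estimate
    at that new root is the prediction. The weight records the number of
    empirical tip values used.
    """
    traits = _as_tip_traits(traits)
    all_tips = tree.tip_labels()
    known = [t for t in all_tips if t in traits]
    unknown = [t for t in all_tips if t not in traits]
    if not known:
        raise EstimationError("no tip has an empirical trait value")
    out: Dict[str, TraitEstimate] = {}
    if not unknown:
        return out
    if len(known) == 1:
        only = traits[known[0]]
        for q in unknown:
            out[q] = TraitEstimate(only.gcn, only.weight, False)
        return out
    for query in unknown:
        sub = tree.tree.extract_tree_with_taxa_labels(set(known) | {query})
        qnode = next(l for l in sub.leaf_node_iter()
                     if l.taxon.label == query)
        attach = qnode.parent_node
        sub.reseed_at(attach, suppress_unifurcations=False,
                      collapse_unrooted_basal_bifurcation=False)
        attach.remove_child(qnode)
        x, w = _root_estimate(sub, traits)
        out[query] = TraitEstimate(x, w, False)
    return out


def aggregate_taxon_gcn(estimates: Mapping[str, TraitEstimate],
                        taxon_labels: Mapping[str, str]) -> Dict[str, float]:
    """Combine node estimates into one GCN per taxon.

    ``taxon_labels`` maps node/tip keys to taxon labels (several nodes may
    share one taxon). Within a taxon, reconstructed estimates are discarded
    whenever at least one empirical value is present; the survivors are
    combined by a weighted mean using their empirical-tip-count weights.
    """
    groups: Dict[str, list] = {}
    for key, taxon in taxon_labels.items():
        if key in estimates:
            groups.setdefault(taxon, []).append(estimates[key])
    out = {}
    for taxon, ests in groups.items():
        if any(e.empirical for e in ests):
            ests = [e for e in ests if e.empirical]
        wsum = sum(e.weight for e in ests)
        out[taxon] = sum(e.gcn * e.weight for e in ests) / wsum
    return out


@dataclass
class GcnLookup:
    """Pre-computed GCN lookup: taxon-ID keyed and taxonomic-string keyed."""

    id_map: Dict[str, float] = field(default_factory=dict)
    string_map: Dict[str, float] = field(default_factory=dict)

    def get_by_id(self, taxon_id: str) -> Optional[float]:
        return self.id_map.get(taxon_id)

    def get_by_string(self, taxonomy: str) -> Optional[float]:
        """Look up a taxonomic string, stripping the deepest rank until a
        match is found (mirrors the nesting of the phylogeny)."""
        if not taxonomy:
            return None
        ranks = [r.strip() for r in taxonomy.split(";")]
        while ranks:
            key = "; ".join(ranks)
            if key in self.string_map:
                return self.string_map[key]
            ranks.pop()
        return None

    def write(self, id_path, string_path) -> None:
        """Serialize both maps as tab-delimited files with '#' headers."""
        for path, header, mapping in (
                (id_path, "#taxon_id\tgcn_estimate", self.id_map),
                (string_path, "#taxonomic_string\tgcn_estimate", self.string_map)):
            with open(path, "w") as fh:
                fh.write(header + "\n")
                for key in sorted(mapping):
                    fh.write(f"{key}\t{mapping[key]:.10g}\n")

    @classmethod
    def read(cls, id_path=None, string_path=None) -> "GcnLookup":
        def load(path):
            if path is None:
                return {}
            df = pd.read_csv(path, sep="\t", comment=None, header=None,
                             skiprows=1, names=["key", "gcn"])
            return dict(zip(df["key"].astype(str), df["gcn"].astype(float)))
        return cls(id_map=load(id_path), string_map=load(string_path))


def _normalize_string_key(taxonomy: str) -> str:
    return "; ".join(r.strip() for r in taxonomy.split(";"))


def build_lookup(tree: TraitTree, traits: Mapping,
                 taxon_labels: Optional[Mapping[str, str]] = None) -> GcnLookup:
    """Run the full pre-computation: tip averages, ancestral states, tip
    predictions, and taxon aggregation; returns the combined lookup.

    The ID map holds one entry per tip (empirical mean or rerooted-PIC
    prediction) and per labelled internal node (ancestral estimate). The
    string map holds the aggregated per-taxon values for the labels in
    ``taxon_labels`` (defaults to the tree's internal-node labels; tips with
    a taxon label contribute their own estimates too).
    """
    traits = _as_tip_traits(traits)
    preds = predict_unknown_tips(tree, traits)
    # ancestral states on the full tree from empirical + predicted tip values,
    # so every labelled node (even ones pruned from the empirical backbone)
    # receives an estimate
    combined = dict(traits)
    combined.update({q: TipTrait(e.gcn, e.weight) for q, e in preds.items()})
    estimates: Dict[str, TraitEstimate] = dict(
        pic_ancestral_states(tree, combined))
    estimates.update(preds)
    for tip, t in traits.items():
        estimates[tip] = TraitEstimate(t.gcn, t.weight, True)
    id_map = {}
    for key, est in estimates.items():
        id_map[key] = est.gcn
    if taxon_labels is None:
        taxon_labels = {k: k for k in tree.taxon_labels()}
    taxon_labels = {k: _normalize_string_key(v) for k, v in taxon_labels.items()}
    string_map = aggregate_taxon_gcn(estimates, taxon_labels)
    return GcnLookup(id_map=id_map, string_map=string_map)


def pic_ancestral_states_pruned(tree: TraitTree, traits: Mapping) -> Dict[str, TraitEstimate]:
    """PIC ancestral states computed on the tree pruned to trait-bearing
    tips, with estimates reported under the original node labels.

    Convenience for trees where only a subset of tips carries empirical
    values; nodes dropped by the pruning are absent from the output.
    """
    traits = _as_tip_traits(traits)
    known = [t for t in tree.tip_labels() if t in traits]
    if not known:
        raise EstimationError("no tip has an empirical trait value")
    if len(known) == 1:
        t = traits[known[0]]
        return {known[0]: TraitEstimate(t.gcn, t.weight, True)}
    sub = tree.tree.extract_tree_with_taxa_labels(set(known))
    return pic_ancestral_states(TraitTree(sub), traits)
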