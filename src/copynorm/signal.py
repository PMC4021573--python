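"""Phylogenetic signal in a tip trait via Pagel's lambda.

Under Brownian motion the tip values are multivariate normal with
covariance C_ij equal to the shared path length from the root to the most
recent common ancestor of tips i and j. Pagel's lambda multiplies the
off-diagonal entries of C by a factor in [0, 1]: lambda = 0 means the trait
is independent of the tree, lambda = 1 means full Brownian signal. The
maximum-likelihood lambda is found by bounded scalar optimization, with the
root state and the Brownian rate profiled out analytically by generalized
least squares at each candidate lambda. Significance against lambda = 0 is
a likelihood-ratio test on one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .trait import TraitTree

__all__ = ["LambdaFit", "brownian_covariance", "pagel_lambda_fit",
           "lambda_lrt", "taxonomy_to_tree"]


@dataclass
class LambdaFit:
    """Maximum-likelihood fit of Pagel's lambda.

    ``degenerate`` is True on a star phylogeny, where lambda has no effect
    on the likelihood; lambda_hat is then 0 by convention.
    """

    lambda_hat: float
    sigma2_hat: float
    root_state: float
    loglik: float
    loglik_lambda0: float
    degenerate: bool = False

    def __post_init__(self):
        if self.loglik < self.loglik_lambda0 - 1e-8:
            raise ValueError("fitted log-likelihood below the lambda=0 nested model")


def brownian_covariance(tree: TraitTree) -> Tuple[np.ndarray, list]:
    """Tip covariance under Brownian motion: C_ij = depth of MRCA(i, j).

    Returns the matrix and the tip-label order. Edges with missing lengths
    count as zero.
    """
    t = tree.tree
    labels = tree.tip_labels()
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depth = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    tipsets = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tipsets[node] = [i]
            C[i, i] = depth[node]
        else:
            children = node.child_nodes()
            sets = [tipsets[c] for c in children]
            d = depth[node]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            C[i, j] = C[j, i] = d
            tipsets[node] = [i for s in sets for i in s]
    return C, labels


def _profile_loglik(lam: float, C: np.ndarray, x: np.ndarray):
    """GLS-profiled Brownian log-likelihood at a given lambda."""
    n = len(x)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    cf = cho_factor(V, lower=True)
    one = np.ones(n)
    Vi1 = cho_solve(cf, one)
    Vix = cho_solve(cf, x)
    mu = (one @ Vix) / (one @ Vi1)
    r = x - mu
    sigma2 = (r @ cho_solve(cf, r)) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, mu, sigma2


def pagel_lambda_fit(tree: TraitTree, traits: Mapping[str, float],
                     xtol: float = 1e-6) -> LambdaFit:
    """Fit Pagel's lambda in [0, 1] for a trait observed on every tip.

    ``traits`` maps tip label to trait value; all tips must be present and
    the trait must not be constant.
    """
    C, labels = brownian_covariance(tree)
    missing = [l for l in labels if l not in traits]
    if missing:
        raise ValueError(f"tips without trait values: {missing[:5]}")
    if len(labels) < 3:
        raise ValueError("need at least 3 tips")
    x = np.array([float(traits[l]) for l in labels])
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; variance is degenerate")

    off = C - np.diag(np.diag(C))
    ll0, mu0, s20 = _profile_loglik(0.0, C, x)
    if np.max(np.abs(off)) <= 1e-12 * max(np.max(np.diag(C)), 1.0):
        # star phylogeny: lambda unidentifiable, report the degeneracy
        return LambdaFit(0.0, s20, mu0, ll0, ll0, degenerate=True)

    res = optimize.minimize_scalar(lambda lam: -_profile_loglik(lam, C, x)[0],
                                   bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": xtol})
    # guard against boundary misses of the bounded optimizer
    cands = [(res.x, -res.fun)]
    for lam in (0.0, 1.0):
        cands.append((lam, _profile_loglik(lam, C, x)[0]))
    lam_hat, ll_hat = max(cands, key=lambda c: c[1])
    _, mu, s2 = _profile_loglik(lam_hat, C, x)
    return LambdaFit(float(lam_hat), float(s2), float(mu),
                     float(ll_hat), float(ll0))


def lambda_lrt(fit: LambdaFit) -> Tuple[float, float]:
    """Likelihood-ratio test of lambda = 0: returns (statistic, p).

    statistic = 2 (loglik - loglik_lambda0); p is the upper tail of a
    chi-square with 1 degree of freedom.
    """
    stat = max(0.0, 2.0 * (fit.loglik - fit.loglik_lambda0))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


def taxonomy_to_tree(taxonomies: Mapping[str, str],
                     branch_length: float = 1.0) -> TraitTree:
    """Build a uniform-branch-length tree from taxonomic strings.

    Each entry maps a tip label to a semicolon-separated taxonomic string;
    shared rank prefixes become shared internal nodes, every edge gets the
    same arbitrary length (default 1.0). Lets the lambda statistic be
    computed on a taxonomy treated as a (less resolved) phylogeny.
    """
    import dendropy
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = {(): tree.seed_node}
    for tip, taxo in taxonomies.items():
        ranks = tuple(r.strip() for r in taxo.split(";") if r.strip())
        for i in range(1, len(ranks) + 1):
            key = ranks[:i]
            if key not in nodes:
                child = dendropy.Node(label=ranks[i - 1])
                child.edge.length = branch_length
                nodes[key[:-1]].add_child(child)
                nodes[key] = child
        leaf = dendropy.Node()
        leaf.taxon = taxon_ns.new_taxon(tip)
        leaf.edge.length = branch_length
        nodes[ranks].add_child(leaf)
    return TraitTree(tree)
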