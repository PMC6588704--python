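"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's pruning/posterior machinery: they
enumerate every assignment of states to non-observed nodes and sum joint
probabilities directly, so they are exact (and exponentially slow) on the
tiny instances the tests use.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def _tree_edges(phy):
    """List of (parent_node, child_node) plus the node list, via dendropy."""
    edges = []
    for node in phy.tree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append((node, child))
    return edges


def enumeration_site_likelihood(phy, model, leaf_states: dict[str, str], rate: float = 1.0) -> float:
    """Exact site likelihood by summing over all latent-node state assignments.

    ``leaf_states`` maps species to a character; a missing character (one the
    alphabet does not score) makes that leaf latent too.
    """
    states = model.alphabet.states
    pi = model.frequencies
    edges = _tree_edges(phy)
    kernels = {id(c): model.transition_matrix((c.edge.length or 0.0) * rate) for _, c in edges}

    nodes = list(phy.tree.preorder_node_iter())
    fixed: dict[int, int] = {}
    latent: list = []
    for n in nodes:
        if n.is_leaf():
            idx = model.alphabet.index(leaf_states[n.taxon.label])
            if idx >= 0:
                fixed[id(n)] = idx
            else:
                latent.append(n)
        else:
            latent.append(n)

    root = phy.tree.seed_node
    total = 0.0
    for combo in itertools.product(range(len(states)), repeat=len(latent)):
        assign = dict(fixed)
        for node, s in zip(latent, combo):
            assign[id(node)] = s
        p = pi[assign[id(root)]]
        for parent, child in edges:
            p *= kernels[id(child)][assign[id(parent)], assign[id(child)]]
        total += p
    return total


def enumeration_gamma_likelihood(phy, model, leaf_states) -> float:
    """Category-averaged exact site likelihood."""
    rates = model.category_rates
    return float(
        np.mean([enumeration_site_likelihood(phy, model, leaf_states, r) for r in rates])
    )


def enumeration_posterior(phy, model, leaf_states, node_taxa: list[str] | None) -> np.ndarray:
    """Exact marginal posterior at one node by Bayes over enumerated assignments.

    ``node_taxa`` selects the MRCA of those leaves; ``None`` selects the root.
    Gamma categories are averaged with equal prior weight.
    """
    states = model.alphabet.states
    pi = model.frequencies
    edges = _tree_edges(phy)
    nodes = list(phy.tree.preorder_node_iter())
    root = phy.tree.seed_node
    if node_taxa is None:
        target = root
    else:
        target = phy.tree.mrca(taxon_labels=node_taxa)

    fixed: dict[int, int] = {}
    latent: list = []
    for n in nodes:
        if n.is_leaf():
            idx = model.alphabet.index(leaf_states[n.taxon.label])
            if idx >= 0:
                fixed[id(n)] = idx
                continue
        latent.append(n)

    joint = np.zeros(len(states))
    for rate in model.category_rates:
        kernels = {
            id(c): model.transition_matrix((c.edge.length or 0.0) * rate) for _, c in edges
        }
        for combo in itertools.product(range(len(states)), repeat=len(latent)):
            assign = dict(fixed)
            for node, s in zip(latent, combo):
                assign[id(node)] = s
            p = pi[assign[id(root)]]
            for parent, child in edges:
                p *= kernels[id(child)][assign[id(parent)], assign[id(child)]]
            joint[assign[id(target)]] += p
    return joint / joint.sum()


# ---------------------------------------------------------------------- #


def fisher_two_sided(a: int, fg_total: int, b: int, bg_total: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration over all tables."""
    n = fg_total + bg_total
    k = a + b  # carriers in either group
    denom = comb(n, k)

    def point_prob(x: int) -> float:
        if x < 0 or x > fg_total or k - x < 0 or k - x > bg_total:
            return 0.0
        return comb(fg_total, x) * comb(bg_total, k - x) / denom

    p_obs = point_prob(a)
    return sum(
        p for x in range(0, min(fg_total, k) + 1)
        if (p := point_prob(x)) <= p_obs * (1 + 1e-12)
    )


def expected_convergence_brute(recon, pair: tuple[str, str]) -> float:
    """Expected same-derived-state substitution count for one branch pair by
    explicit triple loops over (parent state i, parent state j, derived d)."""
    itree = recon.tree_index
    model = recon.model
    n = model.n_states
    total = 0.0
    for s in range(recon.n_sites):
        r = recon.site_rates[s]
        term = 0.0
        ia, ib = (itree.leaf_index[x] for x in pair)
        Pa = model.transition_matrix(itree.lengths[ia] * r)
        Pb = model.transition_matrix(itree.lengths[ib] * r)
        post_a = recon.posteriors[itree.parent[ia]][s]
        post_b = recon.posteriors[itree.parent[ib]][s]
        for d in range(n):
            pa = sum(post_a[i] * Pa[i, d] for i in range(n) if i != d)
            pb = sum(post_b[j] * Pb[j, d] for j in range(n) if j != d)
            term += pa * pb
        total += term
    return total
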