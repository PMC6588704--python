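"""Felsenstein pruning and marginal ancestral reconstruction.

The per-site likelihood under a reversible model with K equal-weight
discrete-gamma categories is

    L(s) = (1/K) sum_c  sum_a pi_a * C_a^root(s | rate r_c)

where C^root are the pruned conditional likelihoods computed bottom-up with
branch kernels exp(Q * t * r_c).  Marginal posteriors at internal nodes come
from an inside-outside pass per category, mixed across categories with
weights proportional to each category's site likelihood; the per-site
relative rate is the posterior-mean category rate.

All site indices are 0-based internally; public result objects translate to
the package's 1-based alignment-column convention where relevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .core_io import LabeledAlignment, LabelError, Phylogeny
from .models import SubstitutionModel

__all__ = [
    "IndexedTree",
    "AncestralReconstruction",
    "prune_likelihood",
    "marginal_ancestral",
    "optimize_tree_scale",
    "fit_gamma_shape",
]


class IndexedTree:
    """Array-indexed view of a rooted phylogeny (postorder; root last)."""

    def __init__(self, phy: Phylogeny):
        self.phylogeny = phy
        nodes = list(phy.tree.postorder_node_iter())
        self.nodes: list[dendropy.Node] = nodes
        index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root_index = self.n_nodes - 1
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.lengths = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.leaf_index: dict[str, int] = {}
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                self.parent[i] = index[id(n.parent_node)]
                self.children[self.parent[i]].append(i)
                self.lengths[i] = n.edge.length or 0.0
            if n.is_leaf():
                self.leaf_index[n.taxon.label] = i
        self.is_leaf = np.array([n.is_leaf() for n in nodes])
        self.internal_indices = np.nonzero(~self.is_leaf)[0]

    def mrca_index(self, taxa: list[str]) -> int:
        """Index of the most recent common ancestor of the given leaves."""
        try:
            idxs = [self.leaf_index[t] for t in taxa]
        except KeyError as exc:
            raise LabelError(f"taxon {exc.args[0]!r} not in tree") from None
        paths = []
        for i in idxs:
            path = []
            while i != -1:
                path.append(i)
                i = self.parent[i]
            paths.append(set(path))
        common = set.intersection(*paths)
        # Deepest common node = the one whose ancestor chain is longest.
        def depth(i: int) -> int:
            d = 0
            while self.parent[i] != -1:
                i = self.parent[i]
                d += 1
            return d
        return max(common, key=depth)


def _leaf_matrix(aln: LabeledAlignment, itree: IndexedTree) -> np.ndarray:
    """(n_nodes, n_sites) observed state indices; -1 for internal or missing."""
    obs = np.full((itree.n_nodes, aln.n_sites), -1, dtype=np.int64)
    states = aln.state_indices()
    for row, sp in enumerate(aln.species):
        obs[itree.leaf_index[sp]] = states[row]
    return obs


def _inside_pass(
    itree: IndexedTree,
    obs: np.ndarray,
    kernels: np.ndarray,
    n_states: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pruned conditionals for one rate category.

    Returns (partials, log_scale, up_messages) where ``up_messages[i]`` is the
    message from node i to its parent and ``log_scale[s]`` accumulates the
    per-site rescaling applied to keep partials in floating range.
    """
    n_sites = obs.shape[1]
    partials = np.empty((itree.n_nodes, n_sites, n_states))
    up = np.empty_like(partials)
    log_scale = np.zeros(n_sites)
    for i in range(itree.n_nodes):
        if itree.is_leaf[i]:
            part = np.zeros((n_sites, n_states))
            states = obs[i]
            known = states >= 0
            part[known, states[known]] = 1.0
            part[~known] = 1.0  # missing data: flat conditional
        else:
            part = np.ones((n_sites, n_states))
            for c in itree.children[i]:
                part *= up[c]
            mx = part.max(axis=1)
            mx[mx == 0] = 1.0  # impossible site under this category; keep zeros
            part /= mx[:, None]
            log_scale += np.log(mx)
        partials[i] = part
        if itree.parent[i] != -1:
            up[i] = part @ kernels[i].T
    return partials, log_scale, up


def _category_kernels(itree: IndexedTree, model: SubstitutionModel, rate: float) -> np.ndarray:
    return model.transition_matrices(itree.lengths * rate)


@dataclass
class AncestralReconstruction:
    """Marginal posteriors at every node, mixed over rate categories."""

    tree_index: IndexedTree
    model: SubstitutionModel
    alignment: LabeledAlignment
    posteriors: np.ndarray  # (n_nodes, n_sites, n_states)
    site_log_likelihoods: np.ndarray  # (n_sites,)
    category_weights: np.ndarray  # (n_sites, K) posterior category probabilities
    site_rates: np.ndarray  # (n_sites,) posterior-mean relative rates

    @property
    def n_sites(self) -> int:
        return self.posteriors.shape[1]

    def posterior_at(self, node_index: int) -> np.ndarray:
        return self.posteriors[node_index]

    def map_states(self) -> tuple[np.ndarray, np.ndarray]:
        """(states, tie_flags): maximum-posterior state index per node and site.

        Posterior ties are broken by fixed alphabet order (argmax takes the
        first maximum) and flagged.
        """
        states = self.posteriors.argmax(axis=2)
        mx = self.posteriors.max(axis=2)
        ties = (np.isclose(self.posteriors, mx[..., None], rtol=0, atol=1e-12).sum(axis=2)) > 1
        return states, ties

    def root_posterior(self) -> np.ndarray:
        return self.posteriors[self.tree_index.root_index]

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods.sum())


def prune_likelihood(
    aln: LabeledAlignment,
    phy: Phylogeny,
    model: SubstitutionModel,
) -> np.ndarray:
    """Per-site log-likelihoods by Felsenstein pruning (gamma-mixed)."""
    phy.check_leaves_match(aln)
    itree = IndexedTree(phy)
    obs = _leaf_matrix(aln, itree)
    n_states = model.n_states
    pi = model.frequencies
    rates = model.category_rates
    K = len(rates)
    logL = np.empty((K, aln.n_sites))
    for c, r in enumerate(rates):
        kernels = _category_kernels(itree, model, r)
        partials, log_scale, _ = _inside_pass(itree, obs, kernels, n_states)
        root = partials[itree.root_index] @ pi
        with np.errstate(divide="ignore"):
            logL[c] = np.log(root) + log_scale
    return logsumexp(logL, axis=0) - np.log(K)


def marginal_ancestral(
    aln: LabeledAlignment,
    phy: Phylogeny,
    model: SubstitutionModel,
) -> AncestralReconstruction:
    """Marginal ancestral reconstruction at every node (inside-outside)."""
    phy.check_leaves_match(aln)
    itree = IndexedTree(phy)
    obs = _leaf_matrix(aln, itree)
    n_states, n_sites = model.n_states, aln.n_sites
    pi = model.frequencies
    rates = model.category_rates
    K = len(rates)

    logL = np.empty((K, n_sites))
    post_by_cat = np.empty((K, itree.n_nodes, n_sites, n_states))

    for c, r in enumerate(rates):
        kernels = _category_kernels(itree, model, r)
        partials, log_scale, up = _inside_pass(itree, obs, kernels, n_states)
        root_like = partials[itree.root_index] @ pi
        with np.errstate(divide="ignore"):
            logL[c] = np.log(root_like) + log_scale

        outside = np.empty((itree.n_nodes, n_sites, n_states))
        outside[itree.root_index] = pi[None, :]
        for i in range(itree.n_nodes - 1, -1, -1):  # preorder = reversed postorder
            if itree.is_leaf[i]:
                continue
            for child in itree.children[i]:
                msg = outside[i].copy()
                for sib in itree.children[i]:
                    if sib != child:
                        msg *= up[sib]
                out = msg @ kernels[child]
                norm = out.sum(axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                outside[child] = out / norm

        post = outside * partials
        norm = post.sum(axis=2, keepdims=True)
        norm[norm == 0] = 1.0
        post_by_cat[c] = post / norm

    site_loglik = logsumexp(logL, axis=0) - np.log(K)
    # P(category | site data): softmax of per-category log likelihoods.
    w = np.exp(logL - logsumexp(logL, axis=0, keepdims=True)).T  # (n_sites, K)
    posteriors = np.einsum("sc,cnsk->nsk", w, post_by_cat)
    site_rates = w @ rates

    return AncestralReconstruction(
        tree_index=itree,
        model=model,
        alignment=aln,
        posteriors=posteriors,
        site_log_likelihoods=site_loglik,
        category_weights=w,
        site_rates=site_rates,
    )


# ---------------------------------------------------------------------- #
# Simple 1-D maximum-likelihood refinements


def _scaled(phy: Phylogeny, factor: float) -> Phylogeny:
    scaled = phy.copy()
    for edge in scaled.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return scaled


def optimize_tree_scale(
    aln: LabeledAlignment,
    phy: Phylogeny,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (1e-3, 50.0),
) -> tuple[Phylogeny, float]:
    """Maximise likelihood over a single global branch-length scale factor.

    A deliberate lightweight alternative to per-branch optimisation: the
    convergence test needs branch lengths on roughly the right scale, not a
    full ML tree estimate.  Returns the rescaled tree and the factor.
    """
    def neg_loglik(log_factor: float) -> float:
        return -float(prune_likelihood(aln, _scaled(phy, float(np.exp(log_factor))), model).sum())

    res = minimize_scalar(
        neg_loglik, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded",
        options={"xatol": 1e-4},
    )
    factor = float(np.exp(res.x))
    return _scaled(phy, factor), factor


def fit_gamma_shape(
    aln: LabeledAlignment,
    phy: Phylogeny,
    model: SubstitutionModel,
    n_categories: int = 4,
    bounds: tuple[float, float] = (0.05, 20.0),
) -> tuple[SubstitutionModel, float]:
    """Fit the discrete-gamma shape by 1-D likelihood maximisation."""
    def neg_loglik(log_shape: float) -> float:
        m = model.with_gamma(float(np.exp(log_shape)), n_categories)
        return -float(prune_likelihood(aln, phy, m).sum())

    res = minimize_scalar(
        neg_loglik, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded",
        options={"xatol": 1e-3},
    )
    shape = float(np.exp(res.x))
    return model.with_gamma(shape, n_categories), shape
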