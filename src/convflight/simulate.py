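"""Synthetic phylogenies and alignments with planted convergent substitutions.

Sequences evolve site-independently along a fixed rooted tree under a
reversible substitution model with discrete-gamma rate heterogeneity: the
root is drawn from the stationary frequencies, each site is assigned a rate
category (equal weights), and each branch applies the exact transition
kernel exp(Q * t * r).  Convergence is then planted by overwriting the
chosen derived state into the chosen foreground carriers, which yields an
exact truth table for power and false-positive testing.

Topology variants for robustness analyses are produced by applying, per
designated weak internal branch, one of its nearest-neighbour-interchange
(NNI) rearrangements or none, and deduplicating by unrooted topology.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_io import LabeledAlignment, Phylogeny, SpeciesGroupTable
from .models import SubstitutionModel

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedSite",
    "SimulationConfig",
    "TruthTable",
    "simulate_alignment",
    "make_topology_variants",
    "random_phylogeny",
]


@dataclass(frozen=True)
class PlantedSite:
    site: int  # 1-based alignment column
    derived_state: str
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError("a planted site needs at least one carrier")


@dataclass
class SimulationConfig:
    tree: Phylogeny
    model: SubstitutionModel
    labels: SpeciesGroupTable
    n_sites: int
    planted_sites: list[PlantedSite] = field(default_factory=list)
    seed: int = 0
    missing_fraction: float = 0.0
    gene_id: str = "synthetic_gene"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must lie in [0, 1]")
        sites = [p.site for p in self.planted_sites]
        if len(set(sites)) != len(sites):
            raise ValueError("planted sites must be distinct")
        for p in self.planted_sites:
            if not 1 <= p.site <= self.n_sites:
                raise ValueError(f"planted site {p.site} outside 1..{self.n_sites}")
            if p.derived_state not in self.model.alphabet.states:
                raise ValueError(f"derived state {p.derived_state!r} not in alphabet")
            foreground = set(self.labels.foreground)
            if not p.carriers <= foreground:
                raise ValueError(
                    f"carriers {sorted(p.carriers - foreground)} are not foreground species"
                )


@dataclass
class TruthTable:
    """Ground truth for planted convergence: one row per planted site."""

    frame: pd.DataFrame  # columns: site, ancestral_state, derived_state, carriers

    @property
    def sites(self) -> list[int]:
        return self.frame["site"].tolist()

    def carriers_of(self, site: int) -> frozenset[str]:
        row = self.frame.loc[self.frame["site"] == site]
        if row.empty:
            raise KeyError(f"site {site} not planted")
        return frozenset(row.iloc[0]["carriers"].split(","))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def simulate_alignment(config: SimulationConfig) -> tuple[LabeledAlignment, TruthTable]:
    """Evolve an alignment along the tree, then plant the configured convergence.

    Identical configs (including the seed) produce identical alignments.
    At each planted site the root (ancestral) state is constrained to differ
    from the derived state, so the plant is always a genuine substitution.
    """
    rng = np.random.default_rng(config.seed)
    model = config.model
    tree = config.tree.tree
    n_states = model.n_states
    n_sites = config.n_sites
    pi = model.frequencies

    kernels_ok_checked = False

    # Rate category per site (equal weights).
    k = len(model.category_rates)
    categories = rng.integers(0, k, size=n_sites)

    states: dict[int, np.ndarray] = {}  # node id -> state indices per site
    root = tree.seed_node
    root_states = rng.choice(n_states, size=n_sites, p=pi)

    # Constrain planted-site ancestral states to differ from the derived state.
    state_index = {c: i for i, c in enumerate(model.alphabet.states)}
    for p in config.planted_sites:
        d = state_index[p.derived_state]
        if root_states[p.site - 1] == d:
            q = pi.copy()
            q[d] = 0.0
            q /= q.sum()
            root_states[p.site - 1] = rng.choice(n_states, p=q)
    states[id(root)] = root_states

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        parent_states = states[id(node.parent_node)]
        child = np.empty(n_sites, dtype=np.int64)
        for c in range(k):
            mask = categories == c
            if not mask.any():
                continue
            P = model.transition_matrix(t * model.category_rates[c])
            if not kernels_ok_checked:
                if np.any(P < -1e-12):
                    raise ValueError("transition kernel has negative probabilities")
                kernels_ok_checked = True
            sub_parent = parent_states[mask]
            sub_child = np.empty(sub_parent.shape, dtype=np.int64)
            for s in range(n_states):
                sel = sub_parent == s
                if sel.any():
                    sub_child[sel] = rng.choice(n_states, size=int(sel.sum()), p=P[s])
            child[mask] = sub_child
        states[id(node)] = child

    chars = np.frombuffer(model.alphabet.states.encode("ascii"), dtype="S1")
    leaf_rows: dict[str, np.ndarray] = {}
    for leaf in tree.leaf_node_iter():
        leaf_rows[leaf.taxon.label] = states[id(leaf)].copy()

    # Plant convergence by overwriting carrier states.
    truth_rows = []
    for p in config.planted_sites:
        d = state_index[p.derived_state]
        col = p.site - 1
        for sp in p.carriers:
            leaf_rows[sp][col] = d
        truth_rows.append(
            {
                "site": p.site,
                "ancestral_state": model.alphabet.states[root_states[col]],
                "derived_state": p.derived_state,
                "carriers": ",".join(sorted(p.carriers)),
            }
        )

    seq_arrays = {sp: chars[row].astype("U1") for sp, row in leaf_rows.items()}

    # Mask uniformly random cells to missing.
    if config.missing_fraction > 0:
        species = list(seq_arrays)
        n_cells = len(species) * n_sites
        n_mask = int(round(config.missing_fraction * n_cells))
        flat = rng.choice(n_cells, size=n_mask, replace=False)
        missing_char = "N" if model.alphabet.name == "dna" else "X"
        for cell in flat:
            sp = species[cell // n_sites]
            seq_arrays[sp][cell % n_sites] = missing_char

    sequences = {sp: "".join(arr) for sp, arr in seq_arrays.items()}
    aln = LabeledAlignment(config.gene_id, sequences, config.labels, model.alphabet)
    truth = TruthTable(
        pd.DataFrame(truth_rows, columns=["site", "ancestral_state", "derived_state", "carriers"])
    )
    return aln, truth


# ---------------------------------------------------------------------- #
# Random trees and topology variants


def random_phylogeny(
    species: list[str],
    seed: int = 0,
    mean_branch_length: float = 0.05,
) -> Phylogeny:
    """Random rooted binary tree with species-tree-like branch lengths.

    Topology comes from uniform random joins; branch lengths are uniform in
    [0.5, 1.5] times ``mean_branch_length``.  The bounded spread mimics a
    timetree (no near-zero terminal branches, on which a substitution could
    not be placed by any reconstruction) while still varying lengths.
    """
    if len(species) < 2:
        raise ValueError("need at least two species")
    rng = random.Random(seed)
    np_rng = np.random.default_rng(seed + 1)
    taxa = dendropy.TaxonNamespace(species)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def draw_length() -> float:
        return float(mean_branch_length * np_rng.uniform(0.5, 1.5))

    nodes = []
    for sp in species:
        node = dendropy.Node(taxon=taxa.get_taxon(sp))
        node.edge.length = draw_length()
        nodes.append(node)
    while len(nodes) > 1:
        i, j = rng.sample(range(len(nodes)), 2)
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = draw_length()
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return Phylogeny(tree, name=f"random_{seed}")


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _internal_edge_child(tree: dendropy.Tree, bipartition: frozenset[str]) -> dendropy.Node:
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        if _leafset(node) == bipartition:
            return node
    raise ValueError(f"no internal edge with child-side leaves {sorted(bipartition)}")


def _apply_nni(node: dendropy.Node, which: int) -> None:
    """In place: swap child ``which`` of ``node`` with ``node``'s sibling."""
    parent = node.parent_node
    if parent.parent_node is None and len(parent.child_nodes()) == 2:
        # Swapping across a bifurcating root does not change the unrooted
        # topology; such edges are not usable NNI edges.
        raise ValueError("weak branch is incident to the root; NNI is a no-op there")
    siblings = [c for c in parent.child_nodes() if c is not node]
    if not siblings:
        raise ValueError("edge does not support NNI (no sibling)")
    sib = siblings[0]
    children = node.child_nodes()
    if len(children) < 2:
        raise ValueError("edge child is not internal")
    moved = children[which]
    parent.remove_child(sib)
    node.remove_child(moved)
    parent.add_child(moved)
    node.add_child(sib)


def make_topology_variants(
    phy: Phylogeny,
    weak_branches: list[frozenset[str] | set[str]],
    k: int,
    seed: int = 0,
) -> list[Phylogeny]:
    """Distinct topologies from NNI moves on designated weak internal branches.

    Each weak branch (identified by the leaf set on its child side)
    independently keeps its arrangement or takes one of its two NNI
    rearrangements; all combinations are enumerated, deduplicated under
    unrooted topology comparison, and at most ``k`` distinct trees
    (always including the original) are returned.  Requesting more
    variants than exist returns all that exist with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    weak = [frozenset(b) for b in weak_branches]
    for b in weak:
        node = _internal_edge_child(phy.tree, b)  # validate against the original tree
        parent = node.parent_node
        if parent.parent_node is None and len(parent.child_nodes()) == 2:
            raise ValueError(
                f"weak branch {sorted(b)} is incident to a bifurcating root; "
                "NNI there cannot change the unrooted topology"
            )

    def signature(tree: dendropy.Tree) -> frozenset:
        t = dendropy.Tree(tree)
        t.encode_bipartitions()
        return frozenset(b.split_bitmask for b in t.bipartition_encoding if not b.is_trivial())

    variants: list[Phylogeny] = []
    seen: set[frozenset] = set()

    combos = list(itertools.product((0, 1, 2), repeat=len(weak)))
    # Original (all zeros) first; remaining combos in seeded random order.
    rng = random.Random(seed)
    rest = [c for c in combos if any(c)]
    rng.shuffle(rest)
    for combo in [combos[0] if combos else ()] + rest:
        t = dendropy.Tree(phy.tree)
        # Resolve all weak-edge nodes before rearranging: node references stay
        # valid through the swaps even when bipartitions change.
        nodes = [_internal_edge_child(t, b) for b in weak]
        for node, choice in zip(nodes, combo):
            if choice:
                _apply_nni(node, choice - 1)
        sig = signature(t)
        if sig in seen:
            continue
        seen.add(sig)
        variants.append(Phylogeny(t, name=f"{phy.name}_nni{len(variants)}"))
        if len(variants) == k:
            break

    if len(variants) < k:
        logger.warning(
            "only %d distinct topologies exist for %d weak branches (requested %d)",
            len(variants), len(weak), k,
        )
    return variants
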