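"""Observed vs neutrally expected convergent substitutions (pipeline step 2).

For each pair of foreground branches (by default the terminal branches of
the flight-degenerate species) the expected number of convergent
substitutions under the fitted neutral model is

    E = sum_sites sum_pairs sum_derived d
        [ sum_{i != d} P(parent_1 = i) P(i -> d | t_1 r_s) ]
      * [ sum_{j != d} P(parent_2 = j) P(j -> d | t_2 r_s) ]

with parent-state probabilities from the marginal reconstruction and r_s
the posterior-mean site rate.  Parallel changes (identical parent states)
and convergent changes (different parent states) to the same derived state
are pooled.  The observed count assigns every node its maximum-posterior
state and counts, per site and pair, the event that both branches
substitute to the same derived state.  Significance is the Poisson upper
tail P(X >= observed) at mean E.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .core_io import LabeledAlignment, Phylogeny, SpeciesGroupTable
from .likelihood import AncestralReconstruction, marginal_ancestral, optimize_tree_scale
from .models import SubstitutionModel
from .site_scan import CandidateSite

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceTestResult",
    "foreground_pairs",
    "expected_convergent_count",
    "observed_convergent_count",
    "poisson_significance",
    "confirm_candidates",
    "results_to_frame",
]


@dataclass(frozen=True)
class ConvergenceTestResult:
    gene_id: str
    observed: int
    expected: float
    p_poisson: float
    n_pairs: int
    retained: bool

    def __post_init__(self) -> None:
        if self.expected < 0:
            raise ValueError("expected count must be non-negative")
        if not 0.0 <= self.p_poisson <= 1.0:
            raise ValueError("p_poisson outside [0, 1]")


def foreground_pairs(
    phy: Phylogeny,
    labels: SpeciesGroupTable,
) -> list[tuple[str, str]]:
    """All unordered pairs of flight-degenerate terminal branches."""
    fg = phy.foreground_leaves(labels)
    return [(fg[i], fg[j]) for i in range(len(fg)) for j in range(i + 1, len(fg))]


def _pair_indices(
    recon: AncestralReconstruction, pairs: list[tuple[str, str]]
) -> list[tuple[int, int]]:
    itree = recon.tree_index
    out = []
    for a, b in pairs:
        ia, ib = itree.leaf_index[a], itree.leaf_index[b]
        out.append((ia, ib))
    return out


def _check_not_nested(recon: AncestralReconstruction, ia: int, ib: int) -> None:
    itree = recon.tree_index
    for start, other in ((ia, ib), (ib, ia)):
        i = start
        while i != -1:
            i = itree.parent[i]
            if i == other:
                raise ValueError("foreground pair members must not be nested")


def expected_convergent_count(
    recon: AncestralReconstruction,
    pairs: list[tuple[str, str]],
) -> float:
    """Neutral expectation of same-derived-state substitutions over branch pairs."""
    itree = recon.tree_index
    model = recon.model
    n_sites = recon.n_sites
    idx_pairs = _pair_indices(recon, pairs)
    for ia, ib in idx_pairs:
        _check_not_nested(recon, ia, ib)

    branch_ids = sorted({i for p in idx_pairs for i in p})
    # Per-branch, per-site substitution profile A[b][s, d] =
    #   sum_{i != d} P(parent = i) P(i -> d | t_b r_s).
    profile: dict[int, np.ndarray] = {}
    for b in branch_ids:
        t = itree.lengths[b]
        if t == 0.0:
            profile[b] = np.zeros((n_sites, model.n_states))
            continue
        parent_post = recon.posteriors[itree.parent[b]]  # (n_sites, n_states)
        P = model.transition_matrices(t * recon.site_rates)  # (n_sites, n, n)
        full = np.einsum("si,sid->sd", parent_post, P)
        diag = parent_post * P[:, np.arange(model.n_states), np.arange(model.n_states)]
        profile[b] = full - diag

    total = 0.0
    for ia, ib in idx_pairs:
        total += float((profile[ia] * profile[ib]).sum())
    return total


def observed_convergent_count(
    recon: AncestralReconstruction,
    pairs: list[tuple[str, str]],
) -> int:
    """Count sites where both branches of a pair substitute to the same state.

    Nodes take their maximum-posterior states (leaves with observed data are
    posterior-certain, so this recovers the observed characters); a leaf with
    missing data never scores a substitution.
    """
    itree = recon.tree_index
    idx_pairs = _pair_indices(recon, pairs)
    for ia, ib in idx_pairs:
        _check_not_nested(recon, ia, ib)
    states, ties = recon.map_states()
    n_ties = int(ties[list(itree.internal_indices)].sum())
    if n_ties:
        logger.warning("%d posterior ties broken by alphabet order", n_ties)

    # Leaves with missing observations have flat posteriors; mask them out.
    obs_ok = np.ones_like(states, dtype=bool)
    aln_states = recon.alignment.state_indices()
    for row, sp in enumerate(recon.alignment.species):
        leaf = itree.leaf_index[sp]
        obs_ok[leaf] = aln_states[row] >= 0
        states[leaf][obs_ok[leaf]] = aln_states[row][obs_ok[leaf]]

    count = 0
    for ia, ib in idx_pairs:
        pa, pb = itree.parent[ia], itree.parent[ib]
        sub_a = (states[ia] != states[pa]) & obs_ok[ia]
        sub_b = (states[ib] != states[pb]) & obs_ok[ib]
        same = states[ia] == states[ib]
        count += int((sub_a & sub_b & same).sum())
    return count


def poisson_significance(observed: int, expected: float) -> float:
    """Upper-tail Poisson probability P(X >= observed) at mean ``expected``."""
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if expected < 0:
        raise ValueError("expected count must be non-negative")
    if observed == 0:
        return 1.0
    if expected == 0.0:
        logger.warning("observed %d substitutions with zero neutral expectation", observed)
        return 0.0
    return float(poisson.sf(observed - 1, expected))


def confirm_candidates(
    candidates: list[CandidateSite],
    alignments: dict[str, LabeledAlignment],
    phy: Phylogeny,
    model: SubstitutionModel,
    alpha: float = 0.01,
    plus_f: bool = True,
    optimize_scale: bool = False,
) -> list[ConvergenceTestResult]:
    """Step-2 confirmation: per candidate gene, test observed vs expected counts.

    ``plus_f`` swaps the model's stationary frequencies for the gene's observed
    character frequencies (the +F option).  With ``optimize_scale`` the tree's
    branch lengths are rescaled by a single ML factor per gene first.
    """
    genes = sorted({c.gene_id for c in candidates})
    results: list[ConvergenceTestResult] = []
    for gene in genes:
        try:
            aln = alignments[gene]
        except KeyError:
            raise KeyError(f"candidate gene {gene!r} has no alignment") from None
        gene_model = model.with_frequencies(aln.observed_frequencies(pseudocount=1.0)) if plus_f else model
        tree = phy
        if optimize_scale:
            tree, _ = optimize_tree_scale(aln, phy, gene_model)
        recon = marginal_ancestral(aln, tree, gene_model)
        pairs = foreground_pairs(tree, aln.labels)
        observed = observed_convergent_count(recon, pairs)
        expected = expected_convergent_count(recon, pairs)
        p = poisson_significance(observed, expected)
        results.append(
            ConvergenceTestResult(
                gene_id=gene,
                observed=observed,
                expected=expected,
                p_poisson=p,
                n_pairs=len(pairs),
                retained=p < alpha,
            )
        )
    return results


def results_to_frame(results: list[ConvergenceTestResult]) -> pd.DataFrame:
    cols = ["gene_id", "observed", "expected", "p_poisson", "n_pairs", "retained"]
    return pd.DataFrame([vars(r) for r in results], columns=cols)
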