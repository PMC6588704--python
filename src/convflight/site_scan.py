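"""Per-site two-group convergence scan (pipeline step 1).

For every alignment column the state dominating the flight-degenerate
(foreground) group is tested against the flying (background) group with a
two-sided Fisher's exact test on the 2x2 carrier table.  A site is a
convergent candidate when the dominant foreground state is shared by at
least ``min_shared`` foreground species AND the Fisher p-value falls below
``alpha`` (defaults 7 and 1e-3 for an 8-versus-40 species design; a
replication scan over more genomes raises ``min_shared``, e.g. to 10).

Missing characters (N, gaps) are excluded from both the carrier counts and
the table totals, but the sharing threshold always counts against the full
foreground group size so that heavily masked sites cannot qualify through
small denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core_io import LabeledAlignment

__all__ = [
    "SiteSpectrum",
    "CandidateSite",
    "site_spectrum",
    "fisher_site_test",
    "scan_alignment",
    "candidates_to_frame",
]


@dataclass
class SiteSpectrum:
    """Per-site, per-state carrier counts in each phenotype group."""

    gene_id: str
    states: str
    fg_counts: np.ndarray  # (n_sites, n_states)
    bg_counts: np.ndarray  # (n_sites, n_states)
    fg_size: int  # number of foreground species (full group, missing included)
    bg_size: int

    @property
    def n_sites(self) -> int:
        return self.fg_counts.shape[0]

    def fg_nonmissing(self) -> np.ndarray:
        """Foreground species with data, per site."""
        return self.fg_counts.sum(axis=1)

    def bg_nonmissing(self) -> np.ndarray:
        return self.bg_counts.sum(axis=1)

    def histogram2d(self) -> np.ndarray:
        """Joint frequency spectrum: entry [i, j] counts (site, state) pairs
        carried by exactly i foreground and j background species."""
        H = np.zeros((self.fg_size + 1, self.bg_size + 1), dtype=np.int64)
        np.add.at(H, (self.fg_counts.ravel(), self.bg_counts.ravel()), 1)
        return H


@dataclass(frozen=True)
class CandidateSite:
    gene_id: str
    site: int  # 1-based alignment column
    state: str
    fg_carriers: int
    fg_total: int  # non-missing foreground species at this site
    bg_carriers: int
    bg_total: int
    p_fisher: float
    tie_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fisher <= 1.0:
            raise ValueError("p_fisher outside [0, 1]")
        if self.fg_carriers > self.fg_total or self.bg_carriers > self.bg_total:
            raise ValueError("carrier counts exceed totals")


def site_spectrum(aln: LabeledAlignment) -> SiteSpectrum:
    """Exact per-site state tallies in the two phenotype groups."""
    idx = aln.state_indices()
    species = aln.species
    fg_mask = np.array([aln.labels.group_of(s) == "flight_degenerate" for s in species])
    n_states = aln.alphabet.n_states

    def tally(rows: np.ndarray) -> np.ndarray:
        sub = idx[rows]  # (n_group, n_sites)
        counts = np.zeros((aln.n_sites, n_states), dtype=np.int64)
        for s in range(n_states):
            counts[:, s] = (sub == s).sum(axis=0)
        return counts

    return SiteSpectrum(
        gene_id=aln.gene_id,
        states=aln.alphabet.states,
        fg_counts=tally(fg_mask),
        bg_counts=tally(~fg_mask),
        fg_size=int(fg_mask.sum()),
        bg_size=int((~fg_mask).sum()),
    )


@lru_cache(maxsize=100_000)
def fisher_site_test(fg_carriers: int, fg_total: int, bg_carriers: int, bg_total: int) -> float:
    """Two-sided Fisher exact p for [[fg_c, fg_t-fg_c], [bg_c, bg_t-bg_c]].

    Uses the point-probability criterion (sum over all tables with the given
    margins whose hypergeometric probability does not exceed the observed
    table's).
    """
    for v in (fg_carriers, fg_total, bg_carriers, bg_total):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if fg_carriers > fg_total or bg_carriers > bg_total:
        raise ValueError("carriers cannot exceed totals")
    if fg_total < 1 or bg_total < 1:
        raise ValueError("each group needs at least one scored species")
    table = [
        [fg_carriers, fg_total - fg_carriers],
        [bg_carriers, bg_total - bg_carriers],
    ]
    return float(fisher_exact(table, alternative="two-sided")[1])


def scan_alignment(
    aln: LabeledAlignment,
    min_shared: int = 7,
    alpha: float = 1e-3,
) -> list[CandidateSite]:
    """Step-1 scan: list candidate sites passing the sharing and Fisher filters.

    The candidate state at a site is the state with the maximal foreground
    carrier count; ties are broken by alphabet order and flagged.  Sites where
    either group has no scored species are skipped.
    """
    spec = site_spectrum(aln)
    if min_shared > spec.fg_size:
        raise ValueError(
            f"min_shared={min_shared} exceeds the foreground group size {spec.fg_size}"
        )
    fg_tot = spec.fg_nonmissing()
    bg_tot = spec.bg_nonmissing()
    best = spec.fg_counts.argmax(axis=1)
    best_count = spec.fg_counts.max(axis=1)
    n_best = (spec.fg_counts == best_count[:, None]).sum(axis=1)

    out: list[CandidateSite] = []
    # The sharing filter is cheap; only surviving sites pay for a Fisher test.
    for site0 in np.nonzero((best_count >= min_shared) & (fg_tot > 0) & (bg_tot > 0))[0]:
        s = int(best[site0])
        fg_c = int(spec.fg_counts[site0, s])
        bg_c = int(spec.bg_counts[site0, s])
        p = fisher_site_test(fg_c, int(fg_tot[site0]), bg_c, int(bg_tot[site0]))
        if p < alpha:
            out.append(
                CandidateSite(
                    gene_id=aln.gene_id,
                    site=int(site0) + 1,
                    state=spec.states[s],
                    fg_carriers=fg_c,
                    fg_total=int(fg_tot[site0]),
                    bg_carriers=bg_c,
                    bg_total=int(bg_tot[site0]),
                    p_fisher=p,
                    tie_flag=bool(n_best[site0] > 1),
                )
            )
    return out


def candidates_to_frame(candidates: list[CandidateSite]) -> pd.DataFrame:
    cols = [
        "gene_id", "site", "state", "fg_carriers", "fg_total",
        "bg_carriers", "bg_total", "p_fisher", "tie_flag",
    ]
    return pd.DataFrame([vars(c) for c in candidates], columns=cols)
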