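"""Ancestral reconstruction of focal codons and the genotype->flight map.

Each of the three nucleotide columns of a focal codon (for example the
ATGL residue-321 codon or the ACOT7 residue-197 codon) is reconstructed
marginally; the codon posterior at a node is the product of the three
per-position posteriors, renormalised.  This per-position independence
approximation is transparent and exactly testable; it is not a 61-state
codon substitution model.

The flight-phenotype map follows the two focal residues:

    (ATGL Ser, ACOT7 Ala) -> sustained flyer
    (ATGL Gly, ACOT7 Ala) -> non-sustained flyer
    (ATGL Gly, ACOT7 Val) -> flightless or weak flyer
    anything else          -> unclassified
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core_io import LabeledAlignment, Phylogeny
from .likelihood import marginal_ancestral
from .models import SubstitutionModel

logger = logging.getLogger(__name__)

__all__ = [
    "CodonReconstruction",
    "PhenotypeCall",
    "reconstruct_codon",
    "genotype_to_phenotype",
    "robustness_report",
]

SUSTAINED = "sustained_flyer"
NON_SUSTAINED = "non_sustained_flyer"
FLIGHTLESS = "flightless_or_weak"
UNCLASSIFIED = "unclassified"

_PHENOTYPE_MAP = {
    ("S", "A"): SUSTAINED,
    ("G", "A"): NON_SUSTAINED,
    ("G", "V"): FLIGHTLESS,
}

_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


class ReconstructionError(ValueError):
    """Raised when a codon position carries no scorable data."""


@dataclass
class CodonReconstruction:
    """Per-node codon posteriors for one focal codon."""

    gene_id: str
    start_column: int  # 1-based first nucleotide column of the codon
    node_indices: np.ndarray  # internal node indices into the tree index
    codon_posteriors: np.ndarray  # (n_internal, 64)
    tree_index: "object"

    @property
    def codons(self) -> list[str]:
        return _CODONS

    def best_codon(self, position: int) -> tuple[str, float]:
        """(most probable codon, its posterior probability) for internal node ``position``."""
        row = list(self.node_indices).index(position)
        post = self.codon_posteriors[row]
        best = int(post.argmax())
        return _CODONS[best], float(post[best])

    def root_call(self) -> tuple[str, float]:
        return self.best_codon(int(self.tree_index.root_index))

    def mrca_call(self, taxa: list[str]) -> tuple[str, float]:
        return self.best_codon(self.tree_index.mrca_index(taxa))


@dataclass(frozen=True)
class PhenotypeCall:
    atgl_aa: str
    acot7_aa: str
    phenotype_class: str


def reconstruct_codon(
    aln: LabeledAlignment,
    start_column: int,
    phy: Phylogeny,
    model: SubstitutionModel,
) -> CodonReconstruction:
    """Marginal codon reconstruction from three consecutive alignment columns.

    ``start_column`` is the 1-based first column of the in-frame codon for
    the reference species.  A column at which no species carries a scorable
    nucleotide is a reconstruction error.
    """
    if model.alphabet.name != "dna":
        raise ValueError("codon reconstruction requires a nucleotide model")
    cols = [start_column, start_column + 1, start_column + 2]
    if cols[-1] > aln.n_sites:
        raise IndexError(f"codon starting at column {start_column} runs past the alignment")
    sub = aln.subalignment(cols)
    idx = sub.state_indices()
    for pos in range(3):
        if (idx[:, pos] >= 0).sum() == 0:
            raise ReconstructionError(f"alignment column {cols[pos]} is entirely missing")
    recon = marginal_ancestral(sub, phy, model)
    itree = recon.tree_index
    internal = itree.internal_indices
    pos_post = recon.posteriors[internal]  # (n_internal, 3, 4)
    codon_post = np.einsum("ni,nj,nk->nijk", pos_post[:, 0], pos_post[:, 1], pos_post[:, 2])
    codon_post = codon_post.reshape(len(internal), 64)
    codon_post /= codon_post.sum(axis=1, keepdims=True)
    return CodonReconstruction(
        gene_id=aln.gene_id,
        start_column=start_column,
        node_indices=internal,
        codon_posteriors=codon_post,
        tree_index=itree,
    )


def genotype_to_phenotype(atgl_codon: str, acot7_codon: str) -> PhenotypeCall:
    """Map the two focal codons to a flight-phenotype class via translation."""
    aas = []
    for codon in (atgl_codon, acot7_codon):
        codon = codon.upper()
        if len(codon) != 3 or any(c not in "ACGT" for c in codon):
            raise ValueError(f"not a codon: {codon!r}")
        aa = str(Seq(codon).translate())
        if aa == "*":
            warnings.warn(f"stop codon {codon} at a focal site", stacklevel=2)
        aas.append(aa)
    atgl_aa, acot7_aa = aas
    cls = _PHENOTYPE_MAP.get((atgl_aa, acot7_aa), UNCLASSIFIED)
    return PhenotypeCall(atgl_aa=atgl_aa, acot7_aa=acot7_aa, phenotype_class=cls)


def robustness_report(
    aln: LabeledAlignment,
    atgl_start: int,
    acot7_start: int,
    trees: list[Phylogeny],
    model: SubstitutionModel,
    ancestor_taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Ancestral calls for both focal codons across alternative topologies.

    Reconstructs at the root (or at the MRCA of ``ancestor_taxa``) for each
    supplied tree; trees whose leaf set does not match the alignment are
    skipped with a warning.  Returns one row per usable tree plus agreement
    columns that let the caller count concordant calls.
    """
    rows = []
    for tree in trees:
        if set(tree.leaf_labels) != set(aln.species):
            logger.warning("tree %s skipped: leaf set does not match alignment", tree.name)
            continue
        calls = {}
        for label, start in (("atgl", atgl_start), ("acot7", acot7_start)):
            rec = reconstruct_codon(aln, start, tree, model)
            codon, pp = rec.mrca_call(ancestor_taxa) if ancestor_taxa else rec.root_call()
            calls[f"{label}_codon"] = codon
            calls[f"{label}_pp"] = pp
        pheno = genotype_to_phenotype(calls["atgl_codon"], calls["acot7_codon"])
        rows.append(
            {
                "tree": tree.name,
                **calls,
                "atgl_aa": pheno.atgl_aa,
                "acot7_aa": pheno.acot7_aa,
                "phenotype_class": pheno.phenotype_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tree", "atgl_codon", "atgl_pp", "acot7_codon", "acot7_pp",
            "atgl_aa", "acot7_aa", "phenotype_class",
        ],
    )
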