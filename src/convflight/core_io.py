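"""Alignments, trees and phenotype-group tables: domain types and file IO.

Conventions
-----------
* Site coordinates are 1-based alignment columns everywhere.  The utility
  :func:`column_to_reference_coordinate` converts an alignment column to the
  ungapped 1-based coordinate of a named reference species (columns where the
  reference itself carries a gap or missing character map to ``None``).
* ``N`` and ``-`` (and other ambiguity codes) are missing data for every
  counting operation.
* Trees are rooted; branch lengths are expected substitutions per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import DNA, Alphabet

logger = logging.getLogger(__name__)

FLYING = "flying"
FLIGHT_DEGENERATE = "flight_degenerate"
_GROUPS = (FLYING, FLIGHT_DEGENERATE)


class AlignmentFormatError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


class LabelError(ValueError):
    """Raised when species are missing from, or duplicated in, the label table."""


class TreeFormatError(ValueError):
    """Raised for malformed Newick input."""


# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class SpeciesGroupTable:
    """Maps each species to its phenotype group (flying vs flight-degenerate)."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s: g for s, g in self.groups.items() if g not in _GROUPS}
        if bad:
            raise LabelError(f"unknown group labels: {bad}")
        for g in _GROUPS:
            if g not in self.groups.values():
                raise LabelError(f"no species labelled {g!r}")

    @property
    def species(self) -> list[str]:
        return list(self.groups)

    @property
    def foreground(self) -> list[str]:
        """Flight-degenerate species (the convergence foreground)."""
        return [s for s, g in self.groups.items() if g == FLIGHT_DEGENERATE]

    @property
    def background(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == FLYING]

    def group_of(self, species: str) -> str:
        try:
            return self.groups[species]
        except KeyError:
            raise LabelError(f"species {species!r} absent from the label table") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesGroupTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["species_id", "group"], comment="#")
        dupes = df["species_id"][df["species_id"].duplicated()].tolist()
        if dupes:
            raise LabelError(f"duplicated species in label table: {dupes}")
        return cls(dict(zip(df["species_id"].astype(str), df["group"].astype(str))))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"species_id": list(self.groups), "group": list(self.groups.values())}
        ).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class LabeledAlignment:
    """Equal-length per-species sequences plus the phenotype group table."""

    gene_id: str
    sequences: dict[str, str]
    labels: SpeciesGroupTable
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentFormatError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        unknown = [s for s in self.sequences if s not in self.labels.groups]
        if unknown:
            raise LabelError(f"species not in label table: {unknown}")

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def foreground_species(self) -> list[str]:
        return [s for s in self.sequences if self.labels.group_of(s) == FLIGHT_DEGENERATE]

    @property
    def background_species(self) -> list[str]:
        return [s for s in self.sequences if self.labels.group_of(s) == FLYING]

    def column(self, site: int) -> dict[str, str]:
        """Characters of 1-based alignment column ``site``."""
        if not 1 <= site <= self.n_sites:
            raise IndexError(f"site {site} outside 1..{self.n_sites}")
        return {sp: seq[site - 1] for sp, seq in self.sequences.items()}

    def state_indices(self) -> np.ndarray:
        """(n_species, n_sites) int array of alphabet indices; -1 marks missing."""
        n = self.n_sites
        out = np.empty((len(self.sequences), n), dtype=np.int16)
        lut = np.full(128, -1, dtype=np.int16)
        for i, c in enumerate(self.alphabet.states):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        for row, seq in enumerate(self.sequences.values()):
            out[row] = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        return out

    def subalignment(self, sites: list[int], gene_id: str | None = None) -> "LabeledAlignment":
        """New alignment restricted to the given 1-based columns, in order."""
        for s in sites:
            if not 1 <= s <= self.n_sites:
                raise IndexError(f"site {s} outside 1..{self.n_sites}")
        seqs = {sp: "".join(seq[s - 1] for s in sites) for sp, seq in self.sequences.items()}
        return LabeledAlignment(gene_id or self.gene_id, seqs, self.labels, self.alphabet)

    def observed_frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Empirical state frequencies over all non-missing cells (for +F models)."""
        idx = self.state_indices()
        counts = np.bincount(idx[idx >= 0], minlength=self.alphabet.n_states).astype(float)
        counts += pseudocount
        if counts.sum() == 0:
            raise AlignmentFormatError("alignment contains no scorable characters")
        return counts / counts.sum()


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths; leaves are species ids."""

    tree: dendropy.Tree
    name: str = "tree"

    def __post_init__(self) -> None:
        self.tree.is_rooted = True
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and (not np.isfinite(edge.length) or edge.length < 0):
                raise TreeFormatError(f"invalid branch length {edge.length}")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def foreground_leaves(self, labels: SpeciesGroupTable) -> list[str]:
        """Leaves whose species are flight-degenerate: the default foreground branches."""
        return [s for s in self.leaf_labels if labels.groups.get(s) == FLIGHT_DEGENERATE]

    def check_leaves_match(self, aln: LabeledAlignment) -> None:
        if set(self.leaf_labels) != set(aln.species):
            only_t = set(self.leaf_labels) - set(aln.species)
            only_a = set(aln.species) - set(self.leaf_labels)
            raise LabelError(
                f"leaf set does not match alignment (tree-only: {sorted(only_t)}, "
                f"alignment-only: {sorted(only_a)})"
            )

    def copy(self) -> "Phylogeny":
        return Phylogeny(dendropy.Tree(self.tree), name=self.name)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def reroot_at_outgroup(self, outgroup: str) -> "Phylogeny":
        """Root on the terminal branch of ``outgroup`` (midpoint of that edge)."""
        t = dendropy.Tree(self.tree)
        node = t.find_node_with_taxon_label(outgroup)
        if node is None:
            raise LabelError(f"outgroup {outgroup!r} not found in tree")
        length = node.edge.length or 0.0
        t.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
        return Phylogeny(t, name=self.name)


# ---------------------------------------------------------------------- #
# Readers / writers


def read_labels(path: str | Path) -> SpeciesGroupTable:
    return SpeciesGroupTable.from_tsv(path)


def read_alignment(
    path: str | Path,
    labels: SpeciesGroupTable,
    alphabet: Alphabet = DNA,
    gene_id: str | None = None,
) -> LabeledAlignment:
    """Load an aligned FASTA file; every record must be a labelled species."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise AlignmentFormatError(f"{path}: duplicate record {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return LabeledAlignment(gene_id or path.stem, seqs, labels, alphabet)


def write_alignment(aln: LabeledAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=sp, description="") for sp, seq in aln.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tree(path: str | Path, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a rooted Newick tree; optionally fill in absent branch lengths."""
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError(f"{path}: {exc}") from exc
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            n_missing += 1
            if default_branch_length is not None:
                edge.length = default_branch_length
    if n_missing and default_branch_length is not None:
        logger.warning(
            "%s: %d branches lacked lengths; defaulted to %g", path, n_missing, default_branch_length
        )
    elif n_missing:
        raise TreeFormatError(
            f"{path}: {n_missing} branches lack lengths and no default was supplied"
        )
    return Phylogeny(tree, name=path.stem)


def write_tree(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phy.newick() + "\n")


# ---------------------------------------------------------------------- #
# Coordinate utilities


def column_to_reference_coordinate(aln: LabeledAlignment, reference_species: str) -> dict[int, int | None]:
    """Map each 1-based alignment column to the reference's ungapped 1-based position.

    Columns at which the reference species carries a gap or missing character
    map to ``None`` (they have no coordinate in the reference sequence).
    """
    if reference_species not in aln.sequences:
        raise LabelError(f"reference species {reference_species!r} not in alignment")
    seq = aln.sequences[reference_species]
    out: dict[int, int | None] = {}
    pos = 0
    for col, char in enumerate(seq, start=1):
        if aln.alphabet.is_missing(char):
            out[col] = None
        else:
            pos += 1
            out[col] = pos
    return out


def reference_coordinate_to_column(aln: LabeledAlignment, reference_species: str) -> dict[int, int]:
    """Inverse map: reference ungapped position -> alignment column."""
    fwd = column_to_reference_coordinate(aln, reference_species)
    return {p: c for c, p in fwd.items() if p is not None}


def validate_inputs(aln: LabeledAlignment, phy: Phylogeny, labels: SpeciesGroupTable) -> None:
    """Cross-check alignment, tree and labels; raises on any inconsistency."""
    phy.check_leaves_match(aln)
    for sp in aln.species:
        labels.group_of(sp)
    if not aln.foreground_species:
        raise LabelError("alignment contains no flight-degenerate species")
    if not aln.background_species:
        raise LabelError("alignment contains no flying species")
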