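"""Character alphabets shared across the package.

Site columns are always 1-based alignment coordinates.  Characters listed
in an alphabet's ``missing`` set (gaps, ambiguity codes) are excluded from
every counting and likelihood operation: a missing cell contributes a flat
conditional likelihood and is dropped from both numerator and denominator
of frequency tallies, so it can never create spurious convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Alphabet:
    name: str
    states: str
    missing: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate states in alphabet")
        overlap = set(self.states) & self.missing
        if overlap:
            raise ValueError(f"states double as missing codes: {overlap}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, char: str) -> int:
        """State index for ``char``; -1 for a missing/unknown character."""
        c = char.upper()
        if c in self.missing:
            return -1
        try:
            return self.states.index(c)
        except ValueError:
            return -1

    def is_missing(self, char: str) -> bool:
        return self.index(char) < 0


#: Canonical nucleotide order used throughout (ties in argmax resolve A<C<G<T).
DNA = Alphabet("dna", "ACGT", frozenset("-N?.RYSWKMBDHV"))

#: Amino acids in the order used by empirical rate matrices (ARNDCQEGHILKMFPSTWYV).
PROTEIN = Alphabet("protein", "ARNDCQEGHILKMFPSTWYV", frozenset("-X?.*BZJU"))


def get_alphabet(name: str) -> Alphabet:
    try:
        return {"dna": DNA, "nucleotide": DNA, "protein": PROTEIN, "aa": PROTEIN}[name.lower()]
    except KeyError:
        raise ValueError(f"unknown alphabet {name!r}") from None
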