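"""Reversible substitution models with discrete-gamma rate heterogeneity.

A :class:`SubstitutionModel` holds a state alphabet, an instantaneous rate
matrix Q normalised to one expected substitution per unit branch length at
stationarity, the stationary frequencies pi, and an optional discrete-gamma
set of relative site rates (equal-weight categories whose rates are the
conditional means of the quantile slices of a Gamma(shape, shape)
distribution, hence mean 1).

Transition kernels exp(Q t) are computed through the symmetric
eigendecomposition of diag(pi)^(1/2) Q diag(pi)^(-1/2), which is exact for
any reversible Q and lets a single decomposition serve every branch length
and rate category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alphabets import DNA, PROTEIN, Alphabet
from ._jtt import JTT_FREQUENCIES, JTT_LOWER_TRIANGLE

__all__ = [
    "SubstitutionModel",
    "discrete_gamma_rates",
    "jc69",
    "k80",
    "hky85",
    "gtr",
    "jtt",
]


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates with mean exactly 1.

    Categories are the ``n_categories`` quantile slices of Gamma(shape, shape);
    each category's rate is the conditional mean of its slice (the standard
    mean-per-category discretisation), renormalised so the average is 1 to
    machine precision.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    probs = np.linspace(0.0, 1.0, n_categories + 1)
    bounds = gamma_dist.ppf(probs, shape, scale=1.0 / shape)
    # E[X; X in (l,u)] for X~Gamma(a, rate a) equals I(a+1, a*u) - I(a+1, a*l)
    # with I the regularised lower incomplete gamma; times k for the
    # conditional mean of an equal-probability slice.
    upper = np.where(np.isfinite(bounds[1:]), shape * bounds[1:], np.inf)
    lower = shape * bounds[:-1]
    seg = gammainc(shape + 1.0, np.where(np.isfinite(upper), upper, 1e300)) - gammainc(
        shape + 1.0, lower
    )
    rates = seg * n_categories
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    alphabet: Alphabet
    exchangeability: np.ndarray  # symmetric, zero diagonal
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 1
    name: str = "custom"

    Q: np.ndarray = field(init=False, repr=False)
    category_rates: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.alphabet.n_states
        S = np.asarray(self.exchangeability, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (n, n):
            raise ValueError("exchangeability shape does not match alphabet")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(S < 0) or np.any(np.diag(S) != 0):
            raise ValueError("exchangeabilities must be non-negative with zero diagonal")
        if pi.shape != (n,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be a probability vector over the alphabet")
        if np.any(pi == 0):
            raise ValueError("zero stationary frequencies are not supported")

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        if mu <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        self.Q = Q / mu
        self.frequencies = pi
        self.exchangeability = S

        if self.gamma_shape is None or self.n_categories == 1:
            self.category_rates = np.ones(max(self.n_categories, 1))
        else:
            self.category_rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)

        # Symmetric eigendecomposition for fast kernels.
        sq = np.sqrt(pi)
        B = (self.Q * sq[:, None]) / sq[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sq[:, None]  # D^{-1/2} U
        self._right = eigvec.T * sq[None, :]  # U^T D^{1/2}

    # ------------------------------------------------------------------ #

    @property
    def n_states(self) -> int:
        return self.alphabet.n_states

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows are probability distributions."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t)[None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """Stack of kernels, shape (len(lengths), n, n), one per entry."""
        lengths = np.asarray(lengths, dtype=float)
        if np.any(lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        expo = np.exp(np.multiply.outer(lengths, self._eigval))  # (m, n)
        P = np.einsum("ik,mk,kj->mij", self._left, expo, self._right)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def with_frequencies(self, frequencies: np.ndarray, name_suffix: str = "+F") -> "SubstitutionModel":
        """Same exchangeabilities under new stationary frequencies (the +F option)."""
        return SubstitutionModel(
            alphabet=self.alphabet,
            exchangeability=self.exchangeability,
            frequencies=np.asarray(frequencies, dtype=float),
            gamma_shape=self.gamma_shape,
            n_categories=self.n_categories,
            name=self.name + name_suffix,
        )

    def with_gamma(self, shape: float, n_categories: int = 4) -> "SubstitutionModel":
        return SubstitutionModel(
            alphabet=self.alphabet,
            exchangeability=self.exchangeability,
            frequencies=self.frequencies,
            gamma_shape=shape,
            n_categories=n_categories,
            name=self.name,
        )


# ---------------------------------------------------------------------- #
# Named constructors


def _uniform(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def jc69(gamma_shape: float | None = None, n_categories: int = 1) -> SubstitutionModel:
    """Jukes-Cantor: equal exchangeabilities and frequencies over ACGT."""
    S = np.ones((4, 4)) - np.eye(4)
    return SubstitutionModel(DNA, S, _uniform(4), gamma_shape, n_categories, name="JC69")


def k80(kappa: float = 2.0, gamma_shape: float | None = None, n_categories: int = 1) -> SubstitutionModel:
    """Kimura two-parameter: transition/transversion ratio ``kappa``, equal frequencies."""
    return hky85(kappa, _uniform(4), gamma_shape, n_categories)


def hky85(
    kappa: float = 2.0,
    frequencies: np.ndarray | None = None,
    gamma_shape: float | None = None,
    n_categories: int = 1,
) -> SubstitutionModel:
    """HKY: transitions (A<->G, C<->T) scaled by ``kappa`` over arbitrary frequencies."""
    if frequencies is None:
        frequencies = _uniform(4)
    S = np.ones((4, 4)) - np.eye(4)
    a, c, g, t = range(4)
    for i, j in ((a, g), (c, t)):
        S[i, j] = S[j, i] = kappa
    return SubstitutionModel(DNA, S, frequencies, gamma_shape, n_categories, name="HKY85")


def gtr(
    rates: np.ndarray,
    frequencies: np.ndarray,
    gamma_shape: float | None = None,
    n_categories: int = 1,
) -> SubstitutionModel:
    """General time-reversible nucleotide model.

    ``rates`` are the six exchangeabilities in the order AC, AG, AT, CG, CT, GT.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,):
        raise ValueError("GTR takes six exchangeabilities (AC, AG, AT, CG, CT, GT)")
    S = np.zeros((4, 4))
    S[0, 1] = S[1, 0] = rates[0]
    S[0, 2] = S[2, 0] = rates[1]
    S[0, 3] = S[3, 0] = rates[2]
    S[1, 2] = S[2, 1] = rates[3]
    S[1, 3] = S[3, 1] = rates[4]
    S[2, 3] = S[3, 2] = rates[5]
    return SubstitutionModel(DNA, S, frequencies, gamma_shape, n_categories, name="GTR")


def _jtt_exchangeability() -> np.ndarray:
    S = np.zeros((20, 20))
    it = iter(JTT_LOWER_TRIANGLE)
    for j in range(19):
        for i in range(j + 1, 20):
            v = float(next(it))
            S[i, j] = S[j, i] = v
    return S


def jtt(
    frequencies: np.ndarray | None = None,
    gamma_shape: float | None = None,
    n_categories: int = 1,
) -> SubstitutionModel:
    """JTT empirical amino-acid model; pass observed gene frequencies for JTT+F."""
    pi = np.asarray(JTT_FREQUENCIES if frequencies is None else frequencies, dtype=float)
    pi = pi / pi.sum()
    name = "JTT" if frequencies is None else "JTT+F"
    return SubstitutionModel(PROTEIN, _jtt_exchangeability(), pi, gamma_shape, n_categories, name=name)
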