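"""Positional correlation natural vector (PCNV) of a DNA sequence.

A DNA sequence ``S = s_1 ... s_N`` is summarised by an 18-dimensional real
vector built from the occurrence positions of the four nucleotides:

* the four occurrence counts ``n_A, n_C, n_G, n_T``;
* the four positional means ``kappa_alpha`` (the mean 1-based position of
  each nucleotide's occurrences);
* the four positional variances ``D2_alpha``;
* the six pairwise positional covariances ``cov(alpha, beta)``.

The means, variances and covariances are moments of a *positional
distribution* ``U_alpha``: a length-N step function that is constant between
consecutive occurrences of the nucleotide.  Writing ``p_0 = 0`` and
``p_1 < p_2 < ... < p_n`` for the 1-based occurrence positions of
``alpha``,

    U_alpha(i) = p_j / (p_{j+1} - p_j)     for p_j <= i < p_{j+1}
    U_alpha(i) = p_n / (N - (p_n - 1))     for p_n <= i <= N

so positions before the first occurrence carry 0, and the block sums
telescope: ``sum_i U_alpha(i) = sum_j p_j``.  The moments are

    kappa_alpha     = sum_i U_alpha(i) / n_alpha
    Ubar_alpha      = sum_i U_alpha(i) / N
    cov(alpha,beta) = sum_i (U_alpha(i)-Ubar_alpha)(U_beta(i)-Ubar_beta)
                      / (n_alpha * n_beta)
    D2_alpha        = cov(alpha, alpha)

Note the covariance is normalised by ``n_alpha * n_beta``, not by ``N``;
this is deliberate and is what makes the components commensurate with the
count and mean components of the vector.

Absent nucleotides (``n_alpha = 0``) get an all-zero ``U`` and, by
convention, zero mean, variance and covariances — the natural "no signal"
value, since the defining ratios divide by ``n_alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "NUCLEOTIDES",
    "COMPONENT_NAMES",
    "IUPAC_AMBIGUOUS",
    "InvalidSequenceError",
    "SequenceRecord",
    "PositionList",
    "PositionalDistribution",
    "PCNVector",
    "extract_positions",
    "positional_distribution",
    "positional_mean",
    "positional_covariance",
    "positional_variance",
    "compute_pcnv",
]

NUCLEOTIDES = ("A", "C", "G", "T")

#: Unordered nucleotide pairs in vector order.
_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))

#: Column names of the 18 components, in the fixed vector order.
COMPONENT_NAMES = (
    "nA", "nC", "nG", "nT",
    "kA", "kC", "kG", "kT",
    "D2A", "D2C", "D2G", "D2T",
    "covAC", "covAG", "covAT", "covCG", "covCT", "covGT",
)

#: IUPAC ambiguity codes accepted (besides A/C/G/T) when strict=False.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")

_VALID_CHARS = frozenset(NUCLEOTIDES) | IUPAC_AMBIGUOUS


class InvalidSequenceError(ValueError):
    """Raised for sequences that violate the DNA input contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence with an identifier.

    The sequence is stored uppercase.  ``U`` (RNA) is mapped to ``T`` on
    construction unless ``strict`` is set, in which case any character
    outside {A, C, G, T} is rejected.  IUPAC ambiguity codes are accepted
    by default: they occupy positions (so downstream coordinates are
    unchanged) but contribute to no nucleotide's position list.
    """

    id: str
    seq: str
    strict: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidSequenceError("record id must be a nonempty string")
        seq = self.seq.upper()
        if not self.strict:
            seq = seq.replace("U", "T")
        if not seq:
            raise InvalidSequenceError(f"record {self.id!r}: empty sequence")
        allowed = frozenset(NUCLEOTIDES) if self.strict else _VALID_CHARS
        bad = set(seq) - allowed
        if bad:
            at = min(seq.find(c) for c in bad)
            raise InvalidSequenceError(
                f"record {self.id!r}: invalid character {seq[at]!r} at position {at + 1}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PositionList:
    """The 1-based occurrence positions of one nucleotide in a sequence."""

    nucleotide: str
    positions: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)

    @property
    def array(self) -> np.ndarray:
        """The positions as an int64 array (cached; avoids reconversion on
        megabase-scale genomes)."""
        return self._array

    def __post_init__(self) -> None:
        arr = np.asarray(self.positions, dtype=np.int64)
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "_array", arr)


@dataclass(frozen=True)
class PositionalDistribution:
    """The step-function values ``U_alpha(1..N)`` for one nucleotide."""

    nucleotide: str
    values: np.ndarray  # shape (N,), float64

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def mean_over_N(self) -> float:
        """``Ubar_alpha``: the positional distribution averaged over all N sites."""
        return float(self.values.sum() / self.length)


@dataclass(frozen=True)
class PCNVector:
    """The ordered 18-component descriptor of one sequence.

    Component order: ``(n_A, n_C, n_G, n_T, kappa_A..kappa_T, D2_A..D2_T,
    cov(A,C), cov(A,G), cov(A,T), cov(C,G), cov(C,T), cov(G,T))``.
    """

    components: tuple[float, ...]
    source_id: str
    source_length: int

    def __post_init__(self) -> None:
        if len(self.components) != 18:
            raise ValueError(f"PCNV must have 18 components, got {len(self.components)}")

    def __iter__(self) -> Iterator[float]:
        return iter(self.components)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.components, dtype=np.float64)


def extract_positions(record: SequenceRecord) -> dict[str, PositionList]:
    """Return the four per-nucleotide position lists of a record.

    Positions are 1-based.  Ambiguity codes hold their position (keeping
    later coordinates intact) but appear in no list.
    """
    arr = np.frombuffer(record.seq.encode("ascii"), dtype="S1")
    out: dict[str, PositionList] = {}
    for nuc in NUCLEOTIDES:
        idx = np.flatnonzero(arr == nuc.encode("ascii")) + 1
        out[nuc] = PositionList(nuc, tuple(idx.tolist()))
    return out


def positional_distribution(plist: PositionList, N: int) -> PositionalDistribution:
    """Build the length-N step function ``U_alpha`` from a position list.

    With ``p_0 = 0``, sites in the half-open block ``[p_j, p_{j+1})`` take
    the value ``p_j / (p_{j+1} - p_j)``; sites from the last occurrence to
    the end take ``p_n / (N - (p_n - 1))``.  An absent nucleotide yields an
    all-zero distribution.
    """
    if N < 1:
        raise ValueError("sequence length must be >= 1")
    if plist.positions and not (1 <= plist.positions[0] and plist.positions[-1] <= N):
        raise ValueError("positions out of range [1, N]")
    if not plist.positions:
        return PositionalDistribution(plist.nucleotide, np.zeros(N, dtype=np.float64))
    p = plist.array.astype(np.float64)
    gaps = np.diff(p)
    # zeros before p_1, one constant block per occurrence gap, tail block
    values = np.concatenate(
        [
            np.zeros(int(p[0]) - 1, dtype=np.float64),
            np.repeat(p[:-1] / gaps, gaps.astype(np.intp)),
            np.full(N - int(p[-1]) + 1, p[-1] / (N - (p[-1] - 1))),
        ]
    )
    return PositionalDistribution(plist.nucleotide, values)


def positional_mean(dist: PositionalDistribution, plist: PositionList) -> float:
    """``kappa_alpha = sum_i U_alpha(i) / n_alpha``.

    Because the block sums telescope, this equals the arithmetic mean of
    the occurrence positions.  Returns 0 for an absent nucleotide.
    """
    if plist.count == 0:
        return 0.0
    return float(dist.values.sum() / plist.count)


def positional_covariance(
    distA: PositionalDistribution,
    distB: PositionalDistribution,
    nA: int,
    nB: int,
) -> float:
    """``cov(alpha, beta)``: centred cross-moment of two positional
    distributions, normalised by ``n_alpha * n_beta``.

    Zero when either nucleotide is absent.  Symmetric in its arguments.
    """
    if distA.length != distB.length:
        raise ValueError(
            f"distribution lengths differ: {distA.length} != {distB.length}"
        )
    if nA == 0 or nB == 0:
        return 0.0
    a = distA.values
    b = distB.values
    N = distA.length
    return float(np.dot(a - a.sum() / N, b - b.sum() / N) / (nA * nB))


def positional_variance(dist: PositionalDistribution, n: int) -> float:
    """``D2_alpha = cov(alpha, alpha)``; nonnegative, 0 when absent."""
    return positional_covariance(dist, dist, n, n)


def compute_pcnv(record: SequenceRecord) -> PCNVector:
    """Assemble the 18-dimensional vector for one sequence.

    Layout: 4 counts, 4 positional means, 4 positional variances, then the
    6 covariances in pair order (A,C), (A,G), (A,T), (C,G), (C,T), (G,T).
    """
    N = len(record)
    plists = extract_positions(record)
    dists = {nuc: positional_distribution(plists[nuc], N) for nuc in NUCLEOTIDES}

    counts = [float(plists[nuc].count) for nuc in NUCLEOTIDES]
    means = [positional_mean(dists[nuc], plists[nuc]) for nuc in NUCLEOTIDES]
    variances = [positional_variance(dists[nuc], plists[nuc].count) for nuc in NUCLEOTIDES]
    covs = [
        positional_covariance(dists[a], dists[b], plists[a].count, plists[b].count)
        for a, b in _PAIRS
    ]
    return PCNVector(
        components=tuple(counts + means + variances + covs),
        source_id=record.id,
        source_length=N,
    )
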