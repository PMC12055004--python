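"""The Jones-Taylor-Thornton (JTT) amino-acid substitution model.

The JTT model is an empirical, time-reversible Markov model of amino-acid
replacement estimated from a large collection of closely related protein
pairs (Jones, Taylor & Thornton 1992).  It is specified by a symmetric
matrix of exchangeabilities ``S`` and a vector of equilibrium amino-acid
frequencies ``pi``.  The rate generator is

    Q_ij = S_ij * pi_j   (i != j),     Q_ii = -sum_{j!=i} Q_ij,

rescaled so that the expected number of substitutions per site per unit
branch length at equilibrium is one: -sum_i pi_i Q_ii = 1.  Branch lengths
everywhere in this package are therefore in expected substitutions per site.

The shipped constants are the standard published integer exchangeabilities
and frequencies (the form distributed with PAML's ``jones.dat``), in the
conventional amino-acid order ARNDCQEGHILKMFPSTWYV.

Because the model is reversible, the generator is similar to a symmetric
matrix; transition matrices exp(Q t) are computed through one eigen
decomposition of that symmetrization, so evaluating exp(Q t) for many t
(as the pairwise ML distance optimizer does) costs a few 20x20 matrix
products each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import InvalidParameterError

#: Canonical amino-acid order used throughout (PAML convention).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20

# Published JTT exchangeabilities: lower triangle, column-major, i.e. the
# first 19 values are S[R..V, A], the next 18 are S[N..V, R], and so on.
_JTT_LOWER_COLMAJOR = (
    # column 0 (A)
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9, 11, 298,
    # column 1 (R)
    45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126, 20, 17,
    # column 2 (N)
    528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232, 8, 70, 16,
    # column 3 (D)
    10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46, 31,
    # column 4 (C)
    9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62,
    # column 5 (Q)
    323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20,
    # column 6 (E)
    119, 26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45,
    # column 7 (G)
    23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    # column 8 (H)
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11,
    # column 9 (I)
    229, 21, 479, 89, 10, 40, 245, 9, 32, 961,
    # column 10 (L)
    14, 388, 248, 102, 59, 25, 52, 24, 180,
    # column 11 (K)
    65, 4, 21, 47, 103, 10, 8, 14,
    # column 12 (M)
    43, 16, 29, 226, 24, 18, 323,
    # column 13 (F)
    17, 92, 12, 53, 536, 62,
    # column 14 (P)
    285, 118, 6, 10, 23,
    # column 15 (S)
    477, 35, 63, 38,
    # column 16 (T)
    12, 21, 112,
    # column 17 (W)
    71, 25,
    # column 18 (Y)
    16,
)

# Published JTT equilibrium frequencies (same order); normalized below.
_JTT_FREQUENCIES = (
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
)


def _expand_lower_colmajor(values) -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for col in range(N_STATES - 1):
        for row in range(col + 1, N_STATES):
            s[row, col] = s[col, row] = values[k]
            k += 1
    return s


@dataclass(frozen=True)
class JTTModel:
    """A reversible amino-acid substitution model in generator form.

    Attributes
    ----------
    exchangeabilities : (20, 20) symmetric non-negative array, zero diagonal.
    frequencies : length-20 equilibrium distribution, sums to 1.
    rate_matrix : generator Q normalized to mean rate 1 at equilibrium.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    rate_matrix: np.ndarray = field(init=False, repr=False)
    # eigendecomposition of the pi-symmetrized generator, for exp(Q t)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise InvalidParameterError("exchangeabilities must be a symmetric 20x20 matrix")
        if np.any(s < 0) or np.any(np.diag(s) != 0):
            raise InvalidParameterError("exchangeabilities must be non-negative with zero diagonal")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise InvalidParameterError("frequencies must be 20 positive probabilities")
        pi = pi / pi.sum()

        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(pi @ np.diag(q))  # expected rate at equilibrium
        q /= mu

        # reversible => D^{1/2} Q D^{-1/2} is symmetric with real spectrum
        sqrt_pi = np.sqrt(pi)
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        eigvals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
        right = vecs / sqrt_pi[:, None]
        left = vecs.T * sqrt_pi[None, :]

        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", pi)
        object.__setattr__(self, "rate_matrix", q)
        object.__setattr__(self, "_eigvals", eigvals)
        object.__setattr__(self, "_left", left)
        object.__setattr__(self, "_right", right)

    def transition_matrix(self, t: float) -> np.ndarray:
        """Return P(t) = exp(Q t), row-stochastic to numerical precision.

        Tiny negative entries from round-off are clipped and rows renormalized.
        """
        if not np.isfinite(t) or t < 0:
            raise InvalidParameterError(f"branch length must be finite and >= 0, got {t}")
        if t == 0:
            return np.eye(N_STATES)
        p = (self._right * np.exp(self._eigvals * t)) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def expected_p_distance(self, t: float) -> float:
        """Expected proportion of differing sites between two sequences
        separated by total path length ``t``: 1 - sum_i pi_i P_ii(t)."""
        p = self.transition_matrix(t)
        return float(1.0 - self.frequencies @ np.diag(p))


@lru_cache(maxsize=1)
def jtt_model() -> JTTModel:
    """The shipped JTT model instance (cached)."""
    return JTTModel(_expand_lower_colmajor(_JTT_LOWER_COLMAJOR),
                    np.array(_JTT_FREQUENCIES))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a protein sequence as int8 state indices.

    Gaps ('-', '.') and ambiguous residues (B, Z, X, U, O, J, '*') map to -1
    and are excluded from comparisons by pairwise deletion.
    """
    table = np.full(128, -1, dtype=np.int8)
    for i, aa in enumerate(AMINO_ACIDS):
        table[ord(aa)] = i
        table[ord(aa.lower())] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]
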