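"""Substitution-rate machinery.

A substitution process over a residue alphabet is a continuous-time Markov
chain with rate matrix Q (rows sum to zero, off-diagonals nonnegative) and
stationary ("saturation") frequencies f.  Finite-time conditional
probabilities are P_t(b|a) = (e^{tQ})(a,b), and log-odds scores at divergence
t are S_t(a,b) = log P_t(b|a)/f_b (half bits: 2*log2).

The divergence scale is anchored so that t = 1 corresponds to the source
matrix: the default model takes Q as the (clamped) principal matrix logarithm
of the BLOSUM62 conditional probability matrix, so e^{1*Q} reproduces
BLOSUM62.  A separate substitutions-per-site scale can be reported but is not
used internally.

The BLOSUM62 probabilities are derived from the published integer half-bit
scores by solving for the matrix's implicit scale (Yu-Altschul inversion)
against a background amino-acid composition, the standard route when only the
integer matrix is distributed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

#: Canonical NCBI amino-acid ordering used by score matrices.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Background amino-acid composition (Swiss-Prot average protein composition,
#: the composition conventionally used for protein null models), in
#: AMINO_ACIDS order.  Normalized on use.
BACKGROUND_FREQUENCIES = np.array(
    [
        0.0787945,  # A
        0.0551739,  # R
        0.0405129,  # N
        0.0541444,  # D
        0.0153085,  # C
        0.0393894,  # Q
        0.0677842,  # E
        0.0695828,  # G
        0.0229849,  # H
        0.0590854,  # I
        0.0963728,  # L
        0.0594472,  # K
        0.0237484,  # M
        0.0414065,  # F
        0.0477822,  # P
        0.0657122,  # S
        0.0508868,  # T
        0.0143991,  # W
        0.0304133,  # Y
        0.0669625,  # V
    ]
)


@dataclass
class SubstitutionModel:
    """A reversible-in-practice substitution process.

    Attributes
    ----------
    alphabet : str
        Ordered residue symbols (size K).
    Q : (K, K) ndarray
        Rate matrix in events per unit divergence time; rows sum to 0 and
        off-diagonal entries are >= 0.
    f : (K,) ndarray
        Background / saturation residue frequencies (sums to 1).
    t_scale : str
        Note recording what t = 1 is anchored to.
    """

    alphabet: str
    Q: np.ndarray
    f: np.ndarray
    t_scale: str = "t=1 anchored to the source conditional matrix"
    clamped_mass: float = field(default=0.0, repr=False)

    @property
    def K(self) -> int:
        return len(self.alphabet)

    def index(self, residue: str) -> int:
        return self.alphabet.index(residue)

    # -- finite-time quantities -------------------------------------------

    def conditional_at(self, t: float) -> np.ndarray:
        """Conditional substitution probabilities P_t(b|a) = (e^{tQ})(a,b)."""
        if t < 0:
            raise ValueError(f"divergence time must be >= 0, got {t}")
        P = expm(t * self.Q)
        # numerical cleanup: tiny negative entries from expm round-off
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def joint_at(self, t: float) -> np.ndarray:
        """Joint probabilities P_t(a,b) = f_a P_t(b|a)."""
        return self.f[:, None] * self.conditional_at(t)

    def score_at(self, t: float, half_bit: bool = True) -> np.ndarray:
        """Log-odds scores S_t(a,b) = log P_t(b|a)/f_b.

        In half bits (2*log2) when ``half_bit``, else natural log.  The
        matrix is symmetrized only if the joint f_a P_t(b|a) is symmetric
        (it is, for a reversible Q), in which case symmetry is exact up to
        round-off and enforced by averaging.
        """
        if t <= 0:
            raise ValueError(f"score_at requires t > 0, got {t}")
        P = self.conditional_at(t)
        with np.errstate(divide="ignore"):
            S = np.log(P / self.f[None, :])
        joint = self.f[:, None] * P
        if np.allclose(joint, joint.T, atol=1e-8):
            S = 0.5 * (S + S.T)
        if half_bit:
            S = 2.0 * S / np.log(2.0)
        return S

    def expected_score_at(self, t: float, half_bit: bool = True) -> float:
        """Expected per-position score sum_ab f_a P_t(a,b) S_t(a,b)."""
        return float((self.joint_at(t) * self.score_at(t, half_bit)).sum())

    def fraction_substitutions(self, t: float) -> float:
        """Fraction of substituted positions at divergence t.

        Defined as the off-diagonal joint mass sum_{a != b} f_a P_t(a,b),
        i.e. 1 - sum_a f_a P_t(a|a).  0 at t = 0; -> 1 - sum_a f_a^2 at
        saturation.
        """
        if t < 0:
            raise ValueError(f"divergence time must be >= 0, got {t}")
        P = self.conditional_at(t)
        return float(1.0 - self.f @ np.diag(P))


def rate_from_conditional(P: np.ndarray, f: np.ndarray, alphabet: str = AMINO_ACIDS,
                          t_scale: str | None = None) -> SubstitutionModel:
    """Derive a rate matrix Q = log P from a conditional probability matrix.

    The principal matrix logarithm is taken via eigendecomposition.  Small
    negative off-diagonal artifacts (log of an empirical stochastic matrix is
    not guaranteed to be a rate matrix) are clamped to zero and the diagonal
    rebalanced so that rows sum to zero; the clamped mass is logged.

    Raises
    ------
    ValueError
        If P is not square, rows do not sum to 1 (tolerance 1e-6), or P has
        an eigenvalue with non-positive real part (no real principal log).
    """
    P = np.asarray(P, dtype=float)
    f = np.asarray(f, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"conditional matrix must be square, got {P.shape}")
    rowsum = P.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-6):
        bad = int(np.argmax(np.abs(rowsum - 1.0)))
        raise ValueError(f"row {bad} of conditional matrix sums to {rowsum[bad]!r}, not 1")

    w, V = np.linalg.eig(P)
    if np.any(w.real <= 0):
        bad = w[np.argmin(w.real)]
        raise ValueError(
            f"conditional matrix has eigenvalue {bad} with non-positive real "
            "part; no real principal matrix logarithm exists"
        )
    cond = np.linalg.cond(V)
    if cond > 1e8:
        logger.warning("eigendecomposition ill-conditioned (cond=%.3g); "
                       "falling back to Schur-based logm", cond)
        from scipy.linalg import logm
        Q = np.real(logm(P))
    else:
        Q = (V @ np.diag(np.log(w.astype(complex))) @ np.linalg.inv(V)).real

    # clamp negative off-diagonal artifacts, rebalance diagonal
    off = ~np.eye(len(Q), dtype=bool)
    neg = np.where(off & (Q < 0.0), Q, 0.0)
    clamped = float(-neg.sum())
    if clamped > 0:
        logger.info("clamped %.3g of negative off-diagonal rate mass", clamped)
    Q[off & (Q < 0.0)] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))

    return SubstitutionModel(
        alphabet=alphabet, Q=Q, f=f / f.sum(),
        t_scale=t_scale or "t=1 anchored to the source conditional matrix",
        clamped_mass=clamped,
    )


def probabilize_scores(S: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recover target probabilities implicit in an integer half-bit matrix.

    Solves for the scale lambda such that sum_ab f_a f_b 2^{lambda S_ab} = 1
    (Yu-Altschul inversion given a background composition), then
    q_ab = f_a f_b 2^{lambda S_ab}.

    Returns
    -------
    P_cond : (K, K) ndarray
        Conditional probabilities q_ab / marginal_a.
    marginals : (K,) ndarray
        Row marginals of the joint (the composition actually implied by the
        matrix; these, not f, are stationary under P_cond).
    """
    S = np.asarray(S, dtype=float)
    f = np.asarray(f, dtype=float)
    f = f / f.sum()
    ff = np.outer(f, f)

    def total(lam: float) -> float:
        return float((ff * np.exp2(lam * S)).sum()) - 1.0

    # lambda in (0, 1/2]: 1/2 would be an exact half-bit matrix
    lam = brentq(total, 1e-9, 0.75)
    joint = ff * np.exp2(lam * S)
    joint /= joint.sum()
    marginals = joint.sum(axis=1)
    return joint / marginals[:, None], marginals


@lru_cache(maxsize=1)
def blosum62_model() -> SubstitutionModel:
    """The default model: Q = log of the BLOSUM62 conditional matrix.

    Probabilities are recovered from the published integer scores against
    BACKGROUND_FREQUENCIES; t = 1 reproduces BLOSUM62.
    """
    from Bio.Align import substitution_matrices

    M = substitution_matrices.load("BLOSUM62")
    idx = [M.alphabet.index(a) for a in AMINO_ACIDS]
    S = np.array([[float(M[i, j]) for j in idx] for i in idx])
    P, marg = probabilize_scores(S, BACKGROUND_FREQUENCIES)
    return rate_from_conditional(P, marg, AMINO_ACIDS,
                                 t_scale="t=1 anchored to BLOSUM62")


def blosum62_scores() -> np.ndarray:
    """The published integer BLOSUM62 half-bit scores in AMINO_ACIDS order."""
    from Bio.Align import substitution_matrices

    M = substitution_matrices.load("BLOSUM62")
    idx = [M.alphabet.index(a) for a in AMINO_ACIDS]
    return np.array([[float(M[i, j]) for j in idx] for i in idx])


def two_letter_model(stay: float = 0.7) -> SubstitutionModel:
    """A tiny two-letter substitution model, handy for exhaustive tests.

    ``stay`` is the probability of no change at t = 1; frequencies are
    uniform, so the process is reversible.
    """
    P = np.array([[stay, 1 - stay], [1 - stay, stay]])
    return rate_from_conditional(P, np.array([0.5, 0.5]), alphabet="ab",
                                 t_scale="t=1 anchored to the 2x2 toy matrix")
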