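"""Divergence-synchronized affine gap costs for Smith-Waterman aligners.

The reversible AFR model is the unique zoo member compatible with the
symmetric insertion/deletion treatment of Smith-Waterman.  Reading a fixed
gap-cost pair (open*, extend*, in half bits) as the AFR joint transition
probabilities at an anchor time t* gives::

    T*_XX = 2^{extend*/2}
    T*_MX = T*_XX / (1 - T*_XX) * 2^{open*/2}
    beta* = T*_MX / (1 - r_M)

and the rate/fragment parameters solve in closed form::

    mu_A = ln[ beta_inf (1 - beta*) / (beta_inf - beta*) ]
    lam  = mu_A beta_inf / (1 - beta_inf)
    r_X  = (T*_XX - beta*) / (1 - beta*)

with beta_inf = lam/(lam + mu_A) the insert-opening probability at infinite
divergence.  r_M and beta_inf are not determined by the anchor and default
to 0.75 and 0.30, which reproduce empirical open/extend pairs collected for
SSEARCH/FASTA at other divergences.  Once solved, open(t) and extend(t) are
evaluated at any divergence time, with substitution scores from the
synchronized matrix exp(t Q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evomodel import AFRParams, lr_beta
from .substitution import SubstitutionModel, blosum62_model

#: Divergence times associated to well-known substitution matrices
#: (PAM10/VT10 through BLOSUM45) on the scale where t = 1 is BLOSUM62.
NOTABLE_TIMES = (0.074, 0.141, 0.229, 0.283, 0.520, 0.567, 0.633, 0.709,
                 0.741, 0.851, 0.995, 1.000, 1.099, 1.135, 1.180, 1.245)


@dataclass
class AnchorSpec:
    """A fixed-time gap-cost anchor: scores in half bits at time t_star."""

    open_star: float = -11.0
    extend_star: float = -1.0
    t_star: float = 1.0
    r_M: float = 0.75
    beta_inf: float = 0.30

    def __post_init__(self) -> None:
        if not 0 <= self.r_M < 1:
            raise ValueError(f"r_M must be in [0, 1), got {self.r_M}")
        if not 0 < self.beta_inf < 0.5:
            raise ValueError(
                f"beta_inf must satisfy 0 < beta_inf < 0.5 (so that lam <= mu_A), "
                f"got {self.beta_inf}"
            )
        if self.t_star <= 0:
            raise ValueError(f"t_star must be > 0, got {self.t_star}")

    @property
    def T_XX(self) -> float:
        return float(2.0 ** (self.extend_star / 2.0))

    @property
    def T_MX(self) -> float:
        txx = self.T_XX
        return float(txx / (1.0 - txx) * 2.0 ** (self.open_star / 2.0))

    @property
    def beta_star(self) -> float:
        return self.T_MX / (1.0 - self.r_M)


def solve_afr_from_anchor(anchor: AnchorSpec) -> AFRParams:
    """Solve the AFR rates and fragment parameters from a gap-cost anchor.

    Raises ValueError naming the violated inequality when the anchor does
    not admit positive rates with lam <= mu_A.
    """
    bstar = anchor.beta_star
    binf = anchor.beta_inf
    txx = anchor.T_XX
    if bstar >= binf:
        raise ValueError(
            f"anchor violates beta* < beta_inf: beta* = {bstar:.4f} >= "
            f"beta_inf = {binf:.4f}"
        )
    if txx <= bstar:
        raise ValueError(
            f"anchor violates T*_XX > beta*: T*_XX = {txx:.4f} <= "
            f"beta* = {bstar:.4f}"
        )
    muA = float(np.log(binf * (1.0 - bstar) / (binf - bstar))) / anchor.t_star
    lam = muA * binf / (1.0 - binf)
    r_X = (txx - bstar) / (1.0 - bstar)
    return AFRParams(lam=lam, muA=muA, r_M=anchor.r_M, r_X=r_X)


def extend_at(params: AFRParams, t: float) -> float:
    """Gap-extend score at divergence t, in half bits (<= 0).

    extend(t) = 2 log2 T^t_XX with T^t_XX = beta_lr(t)(1 - r_X) + r_X.
    """
    if t <= 0:
        raise ValueError(f"extend_at requires t > 0, got {t}")
    beta = lr_beta(t, params.lam, params.muA)
    return float(2.0 * np.log2(beta * (1.0 - params.r_X) + params.r_X))


def open_at(params: AFRParams, t: float) -> float:
    """Gap-open score at divergence t, in half bits (<= 0).

    open(t) = 2 log2 [ T^t_MX (1 - T^t_XX) / T^t_XX ]
            = 2 log2 [ beta(1 - beta)(1 - r_X)(1 - r_M) / (beta(1 - r_X) + r_X) ].
    """
    if t <= 0:
        raise ValueError(f"open_at requires t > 0, got {t}")
    beta = lr_beta(t, params.lam, params.muA)
    txx = beta * (1.0 - params.r_X) + params.r_X
    return float(2.0 * np.log2(
        beta * (1.0 - beta) * (1.0 - params.r_X) * (1.0 - params.r_M) / txx
    ))


def emit_score_table(params: AFRParams,
                     subst: SubstitutionModel | None = None,
                     times: tuple[float, ...] = NOTABLE_TIMES) -> pd.DataFrame:
    """Tabulate (t, % substitutions, open, extend) over a set of times."""
    subst = subst or blosum62_model()
    rows = []
    for t in times:
        rows.append({
            "time": t,
            "pct_substitutions": 100.0 * subst.fraction_substitutions(t),
            "open": open_at(params, t),
            "extend": extend_at(params, t),
        })
    return pd.DataFrame(rows)


def write_score_table(df: pd.DataFrame, path, header_lines: tuple[str, ...] = ()) -> None:
    """Write the score table as TSV with optional provenance header."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def score_matrices_at(params: AFRParams, times, outdir,
                      subst: SubstitutionModel | None = None,
                      integer: bool = False) -> list:
    """Write one NCBI-format substitution matrix per time point.

    Scores are real-valued half bits by default; ``integer`` rounds them
    for aligners that require integers.  Returns the written paths.
    """
    from pathlib import Path

    from .matrixio import write_ncbi_matrix

    subst = subst or blosum62_model()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in times:
        S = subst.score_at(t, half_bit=True)
        if integer:
            S = np.round(S)
        path = outdir / f"matrix_t{t:g}.mat"
        write_ncbi_matrix(
            path, S, subst.alphabet,
            comment=(f"half-bit scores at divergence t={t:g}; "
                     f"open={open_at(params, t):.2f} extend={extend_at(params, t):.2f}"),
            integer=integer,
        )
        paths.append(path)
    return paths
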