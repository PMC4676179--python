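"""Continuous-time insertion/deletion models as three-state pair HMMs.

Every model here describes the relation between an ancestral sequence and a
descendant after divergence time t through a Match/Delete/Insert pair HMM
whose transition probabilities are time-dependent functions of a few rates.
Transitions are built from *elementary probability functions*:

* ``gamma^X(t)`` -- probability that an ancestral residue is deleted by time
  t, given that the preceding element is in state X,
* ``beta^X(t)``  -- probability that an insert opens after state X,
* ``eta(t)``     -- probability that an existing insert extends.

The composite mapping to transitions is::

    t_XI = beta^X                   (X in B, M, D)
    t_XM = (1 - beta^X)(1 - gamma^X)
    t_XD = (1 - beta^X) gamma^X
    t_II = eta + (1 - eta) beta^I
    t_IM = (1 - eta)(1 - beta^I)(1 - gamma^I)
    t_ID = (1 - eta)(1 - beta^I) gamma^I

which is normalized for arbitrary elementary functions and reduces to the
published TKF91 transition matrix with the TKF91 elementary functions.

Model zoo (free parameters):

===== == =======================================================
tkf91  2 lam, mu                   quasi-linear, no memory
tkf92  3 lam, mu, r                fragment derivative of tkf91
li     4 lam, mu, muA, p           linear, ancestral memory
lr     2 lam, muA                  reversible special case of li
aali   6 lam, mu, muA^{M,D,I}, p   affine ancestral deletions
afg    9 aali + r_M, r_D, r_I      fragment derivative of aali
afr    4 lam, muA, r_M, r_X        reversible fragment model
aif    7 aali + r_I                insert-only fragments (profile HMMs)
aga    7 lam, mu, muA^{M,D,I}, s_I, p   time-independent geometric inserts
===== == =======================================================

Single-residue models use the immortal-link birth-death insert process
(birth (n+1)*lam, death n*mu), whose insert length is geometric at all
times; fragment models wrap self-looping states in geometrically sized
indivisible fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# state indices shared across the package
B, M, D, I = 0, 1, 2, 3
STATE_NAMES = "BMDI"


# ---------------------------------------------------------------------------
# parameter types


@dataclass
class SingleResidueParams:
    """Rates of the aali family: insert open/vanish and ancestral deletion.

    ``mu`` is the per-residue vanishing rate of inserted residues; the
    ancestral deletion rate mu_A^X depends on the state of the preceding
    element (mu_A^B = mu_A^M).  ``p`` is the geometric ancestral-length
    parameter.
    """

    lam: float
    mu: float
    muA_M: float
    muA_D: float
    muA_I: float
    p: float

    def __post_init__(self) -> None:
        if min(self.lam, self.mu, self.muA_M, self.muA_D, self.muA_I) < 0:
            raise ValueError("rates must be nonnegative")
        if not 0 <= self.p < 1:
            raise ValueError(f"p must be in [0, 1), got {self.p}")
        if self.lam >= self.mu:
            raise ValueError("insert process requires lam < mu for finite inserts")

    @classmethod
    def li(cls, lam: float, mu: float, muA: float, p: float) -> "SingleResidueParams":
        """Linear model: all ancestral-deletion rates tied."""
        return cls(lam, mu, muA, muA, muA, p)

    @classmethod
    def lr(cls, lam: float, muA: float) -> "SingleResidueParams":
        """Linear Reversible model: mu = lam + muA and p = lam/muA < 1."""
        if lam >= muA:
            raise ValueError("LR requires lam < muA so that p = lam/muA < 1")
        return cls(lam, lam + muA, muA, muA, muA, lam / muA)


@dataclass
class TKFParams:
    """TKF91/TKF92 birth-death parameters; r = 0 gives TKF91."""

    lam: float
    mu: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0 or self.mu <= 0:
            raise ValueError("TKF rates must be nonnegative with mu > 0")
        if self.lam >= self.mu:
            raise ValueError("TKF requires lam < mu (finite expected length)")
        if not 0 <= self.r < 1:
            raise ValueError(f"fragment parameter r must be in [0, 1), got {self.r}")

    @property
    def p(self) -> float:
        return self.lam / self.mu


@dataclass
class FragmentParams:
    """Per-state fragment Bernoulli parameters."""

    r_M: float
    r_D: float
    r_I: float

    def __post_init__(self) -> None:
        for r in (self.r_M, self.r_D, self.r_I):
            if not 0 <= r < 1:
                raise ValueError(f"fragment parameters must be in [0, 1), got {r}")


@dataclass
class GMParams:
    """Geometric model: burst insertions/deletions with distinct open rates.

    The aali model is the special case lam = lamI, mu = muI, vI = vD = 0.
    Used by the microscopic simulator; the GM model has no affine
    macroscopic solution, which is the point of simulating it.
    """

    lam: float
    lamI: float
    mu: float
    muI: float
    vI: float = 0.0
    vD: float = 0.0

    def __post_init__(self) -> None:
        if min(self.lam, self.lamI, self.mu, self.muI) < 0:
            raise ValueError("rates must be nonnegative")
        for v in (self.vI, self.vD):
            if not 0 <= v < 1:
                raise ValueError(f"burst parameters must be in [0, 1), got {v}")


@dataclass
class AGAParams:
    """aga model: aali ancestral machinery, time-independent insert length s_I."""

    lam: float
    mu: float
    muA_M: float
    muA_D: float
    muA_I: float
    sI: float
    p: float

    def __post_init__(self) -> None:
        if min(self.lam, self.mu, self.muA_M, self.muA_D, self.muA_I) < 0:
            raise ValueError("rates must be nonnegative")
        if not 0 <= self.sI < 1:
            raise ValueError(f"s_I must be in [0, 1), got {self.sI}")
        if not 0 <= self.p < 1:
            raise ValueError(f"p must be in [0, 1), got {self.p}")
        if self.lam >= self.mu:
            raise ValueError("insert process requires lam < mu")


@dataclass
class AFRParams:
    """Affine Fragment Reversible model (compatible with Smith-Waterman)."""

    lam: float
    muA: float
    r_M: float
    r_X: float

    def __post_init__(self) -> None:
        if self.lam < 0 or self.muA <= 0:
            raise ValueError("rates must be nonnegative with muA > 0")
        if self.lam >= self.muA:
            raise ValueError("AFR requires lam < muA so that p = lam/muA < 1")
        for r in (self.r_M, self.r_X):
            if not 0 <= r < 1:
                raise ValueError(f"fragment parameters must be in [0, 1), got {r}")

    @property
    def p(self) -> float:
        return self.lam / self.muA


@dataclass
class AFGParams(SingleResidueParams):
    r_M: float = 0.0
    r_D: float = 0.0
    r_I: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        FragmentParams(self.r_M, self.r_D, self.r_I)


@dataclass
class AIFParams(SingleResidueParams):
    r_I: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0 <= self.r_I < 1:
            raise ValueError(f"r_I must be in [0, 1), got {self.r_I}")


#: Free parameters per model (matches the model zoo table).
FREE_PARAMETERS: dict[str, tuple[str, ...]] = {
    "tkf91": ("lam", "mu"),
    "tkf92": ("lam", "mu", "r"),
    "li": ("lam", "mu", "muA", "p"),
    "lr": ("lam", "muA"),
    "aali": ("lam", "mu", "muA_M", "muA_D", "muA_I", "p"),
    "afg": ("lam", "mu", "muA_M", "muA_D", "muA_I", "r_M", "r_D", "r_I", "p"),
    "afr": ("lam", "muA", "r_M", "r_X"),
    "aif": ("lam", "mu", "muA_M", "muA_D", "muA_I", "r_I", "p"),
    "aga": ("lam", "mu", "muA_M", "muA_D", "muA_I", "sI", "p"),
}

MODEL_IDS = tuple(FREE_PARAMETERS)


# ---------------------------------------------------------------------------
# elementary probability functions


def tkf_beta(lam: float, mu: float, t: float) -> float:
    """Insert-opening probability of the immortal-link birth-death process.

    beta(t) = lam (1 - e^{(lam-mu)t}) / (mu - lam e^{(lam-mu)t}); also the
    geometric insert-length parameter at time t (the link's residue count is
    geometric at all times).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if lam >= mu:
        raise ValueError("requires lam < mu")
    e = np.exp((lam - mu) * t)
    return float(lam * (1.0 - e) / (mu - lam * e))


def tkf_gamma_dead(lam: float, mu: float, t: float) -> float:
    """TKF91 insert-opening probability after a *deleted* ancestral residue.

    gamma(t) = 1 - mu (1 - e^{(lam-mu)t}) / ((1 - e^{-mu t})(mu - lam e^{(lam-mu)t})).
    Without the ancestral memory of the aali family, descendants of a dead
    residue collapse into the neighboring insert, so this differs from beta.
    """
    if t <= 0:
        return 0.0
    e = np.exp((lam - mu) * t)
    return float(1.0 - mu * (1.0 - e) / ((1.0 - np.exp(-mu * t)) * (mu - lam * e)))


def lr_beta(t: float, lam: float, muA: float) -> float:
    """LR insert-opening probability.

    beta(t) = beta_inf (1 - e^{-muA t}) / (1 - beta_inf e^{-muA t}) with
    beta_inf = lam/(lam + muA); identical to tkf_beta with mu = lam + muA.
    Strictly increasing from 0 at t = 0 toward beta_inf.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if muA <= 0:
        raise ValueError(f"muA must be > 0, got {muA}")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    binf = lam / (lam + muA)
    e = np.exp(-muA * t)
    return float(binf * (1.0 - e) / (1.0 - binf * e))


@dataclass
class ElementaryFunctions:
    """gamma^X, beta^X (X in B,M,D,I) and eta, evaluated at one time."""

    gamma: np.ndarray  # shape (4,), indexed B,M,D,I
    beta: np.ndarray  # shape (4,)
    eta: float

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        for arr in (self.gamma, self.beta, np.array([self.eta])):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("elementary probabilities must lie in [0, 1]")


def elementary_at(model_id: str, params, t: float) -> ElementaryFunctions:
    """Evaluate a model's elementary probability functions at time t."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    mid = model_id.lower()
    if mid in ("tkf91", "tkf92"):
        lam, mu = params.lam, params.mu
        beta = tkf_beta(lam, mu, t)
        g = 1.0 - np.exp(-mu * t)
        return ElementaryFunctions(
            gamma=np.full(4, g),
            beta=np.array([beta, beta, tkf_gamma_dead(lam, mu, t), 0.0]),
            eta=beta,
        )
    if mid in ("li", "lr", "aali", "afg", "afr", "aif"):
        if mid in ("lr", "afr"):
            muA_val = params.muA if hasattr(params, "muA") else params.muA_M
            lam, mu = params.lam, params.lam + muA_val
            muA = np.full(3, muA_val)
        else:
            lam, mu = params.lam, params.mu
            muA = np.array([params.muA_M, params.muA_D, params.muA_I])
        beta = tkf_beta(lam, mu, t)
        gM, gD, gI = 1.0 - np.exp(-muA * t)
        return ElementaryFunctions(
            gamma=np.array([gM, gM, gD, gI]),  # gamma^B = gamma^M
            beta=np.full(4, beta),
            eta=0.0,
        )
    if mid == "aga":
        beta = tkf_beta(params.lam, params.mu, t)
        gM, gD, gI = 1.0 - np.exp(
            -np.array([params.muA_M, params.muA_D, params.muA_I]) * t
        )
        return ElementaryFunctions(
            gamma=np.array([gM, gM, gD, gI]),
            beta=np.full(4, beta),
            eta=params.sI,
        )
    raise ValueError(f"unknown model id {model_id!r}")


# ---------------------------------------------------------------------------
# transition sets


@dataclass
class TransitionSet:
    """Normalized three-state pair-HMM transitions.

    ``t`` is a (4, 4) array indexed by (from, to) over states B, M, D, I;
    column B is identically zero.  In conditional mode each row sums to 1
    over {M, D, I}.  In joint mode, transitions into the ancestral-advance
    states M and D carry the ancestral-length factor p; the remaining row
    mass is the transition to End.
    """

    t: np.ndarray
    mode: str = "conditional"
    p: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.shape != (4, 4):
            raise ValueError(f"transition array must be (4, 4), got {self.t.shape}")
        if self.mode not in ("conditional", "joint"):
            raise ValueError(f"mode must be conditional or joint, got {self.mode!r}")

    def row_sums(self) -> np.ndarray:
        return self.t.sum(axis=1)

    def end_probabilities(self) -> np.ndarray:
        """Per-state transition-to-End probability (joint mode)."""
        if self.mode != "joint":
            raise ValueError("end probabilities are defined for joint mode")
        return 1.0 - self.t.sum(axis=1)


def assemble_transitions(ef: ElementaryFunctions, p: float | None = None,
                         mode: str = "conditional") -> TransitionSet:
    """Build a normalized TransitionSet from elementary functions.

    The conditional rows sum to 1 identically for arbitrary elementary
    probability functions; joint mode multiplies ancestral-advance
    transitions (into M and D) by p.
    """
    t = np.zeros((4, 4))
    for X in (B, M, D):
        t[X, I] = ef.beta[X]
        t[X, M] = (1.0 - ef.beta[X]) * (1.0 - ef.gamma[X])
        t[X, D] = (1.0 - ef.beta[X]) * ef.gamma[X]
    t[I, I] = ef.eta + (1.0 - ef.eta) * ef.beta[I]
    t[I, M] = (1.0 - ef.eta) * (1.0 - ef.beta[I]) * (1.0 - ef.gamma[I])
    t[I, D] = (1.0 - ef.eta) * (1.0 - ef.beta[I]) * ef.gamma[I]
    if mode == "joint":
        if p is None:
            raise ValueError("joint mode requires the ancestral-length parameter p")
        t[:, M] *= p
        t[:, D] *= p
    return TransitionSet(t=t, mode=mode, p=p)


def fragmentize(ts: TransitionSet, fr: FragmentParams) -> TransitionSet:
    """Wrap the self-looping states M, D, I in geometric fragments.

    Row X is rescaled by (1 - r_X) and r_X is added to the self-loop:
    a_XX -> a_XX (1 - r_X) + r_X, a_XY -> a_XY (1 - r_X).  With all r = 0
    this is the identity.  Works on conditional and joint sets alike (for
    joint sets the fragment is the unit the ancestral-length factor counts).
    """
    t = ts.t.copy()
    for X, r in ((M, fr.r_M), (D, fr.r_D), (I, fr.r_I)):
        t[X, :] *= 1.0 - r
        t[X, X] += r
    return TransitionSet(t=t, mode=ts.mode, p=ts.p)


def _fragment_params(model_id: str, params) -> FragmentParams | None:
    mid = model_id.lower()
    if mid == "tkf92":
        return FragmentParams(params.r, params.r, params.r)
    if mid == "afg":
        return FragmentParams(params.r_M, params.r_D, params.r_I)
    if mid == "afr":
        return FragmentParams(params.r_M, params.r_X, params.r_X)
    if mid == "aif":
        return FragmentParams(0.0, 0.0, params.r_I)
    return None


def ancestral_p(model_id: str, params) -> float:
    """The model's ancestral-length geometric parameter."""
    mid = model_id.lower()
    if mid in ("tkf91", "tkf92"):
        return params.p
    return params.p


def transitions_at(model_id: str, params, t: float,
                   mode: str = "conditional") -> TransitionSet:
    """Transition probabilities of any zoo model at divergence time t.

    Fragment models are fragmentized after the joint conversion in joint
    mode (the ancestral-length factor counts fragments) and after assembly
    in conditional mode.
    """
    ef = elementary_at(model_id, params, t)
    p = ancestral_p(model_id, params) if mode == "joint" else None
    ts = assemble_transitions(ef, p=p, mode=mode)
    fr = _fragment_params(model_id, params)
    if fr is not None:
        ts = fragmentize(ts, fr)
    return ts


def joint_transitions_afr(params: AFRParams, t: float) -> TransitionSet:
    """The symmetric joint AFR transition set of the reversible model.

    T_XX = beta_lr(t)(1 - r_X) + r_X and T_MX = beta_lr(t)(1 - r_M) for
    X in {D, I}; the matrix is invariant under exchanging the two sequence
    roles (D <-> I).
    """
    return transitions_at("afr", params, t, mode="joint")


def reversibility_check(ts: TransitionSet, p: float | None = None
                        ) -> tuple[bool, float]:
    """Is a joint transition set invariant under the insert/delete swap?

    Returns (ok, max violation) with ok True iff
    max |T_XY - T_swap(X)swap(Y)| < 1e-9 where swap exchanges D and I.
    Symmetric joint chains are exactly the ones usable for Smith-Waterman
    style comparison of two extant sequences.
    """
    if ts.mode != "joint":
        raise ValueError("reversibility is a property of the joint chain; "
                         "build the TransitionSet in joint mode")
    swap = np.array([B, M, I, D])
    swapped = ts.t[np.ix_(swap, swap)]
    violation = float(np.abs(ts.t - swapped).max())
    return violation < 1e-9, violation


def free_parameter_count(model_id: str) -> int:
    return len(FREE_PARAMETERS[model_id.lower()])


def make_params(model_id: str, **kw):
    """Construct the parameter object for a model from its free parameters."""
    mid = model_id.lower()
    if mid in ("tkf91", "tkf92"):
        return TKFParams(kw["lam"], kw["mu"], kw.get("r", 0.0))
    if mid == "li":
        return SingleResidueParams.li(kw["lam"], kw["mu"], kw["muA"], kw["p"])
    if mid == "lr":
        return SingleResidueParams.lr(kw["lam"], kw["muA"])
    if mid == "aali":
        return SingleResidueParams(kw["lam"], kw["mu"], kw["muA_M"],
                                   kw["muA_D"], kw["muA_I"], kw["p"])
    if mid == "afg":
        return AFGParams(kw["lam"], kw["mu"], kw["muA_M"], kw["muA_D"],
                         kw["muA_I"], kw["p"], kw["r_M"], kw["r_D"], kw["r_I"])
    if mid == "afr":
        return AFRParams(kw["lam"], kw["muA"], kw["r_M"], kw["r_X"])
    if mid == "aif":
        return AIFParams(kw["lam"], kw["mu"], kw["muA_M"], kw["muA_D"],
                         kw["muA_I"], kw["p"], kw["r_I"])
    if mid == "aga":
        return AGAParams(kw["lam"], kw["mu"], kw["muA_M"], kw["muA_D"],
                         kw["muA_I"], kw["sI"], kw["p"])
    raise ValueError(f"unknown model id {model_id!r}")


def params_to_dict(model_id: str, params) -> dict[str, float]:
    """Free parameters of a model as a plain dict (for writers/CLI)."""
    mid = model_id.lower()
    if mid == "lr":
        return {"lam": params.lam, "muA": params.muA_M}
    if mid == "li":
        return {"lam": params.lam, "mu": params.mu, "muA": params.muA_M,
                "p": params.p}
    out = {}
    for name in FREE_PARAMETERS[mid]:
        out[name] = getattr(params, name)
    return out
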