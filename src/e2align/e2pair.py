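"""Alignment of two extant sequences through an unknown common ancestor.

A standard pair HMM relates an ancestor to one descendant, so it can align
two extant sequences directly only under a reversible model (one sequence
can stand in for the ancestor).  The engine here instead computes

    P(s1, s2 | model, t1, t2)

by summing over all ancestral sequences and evolutionary histories: the
ancestor has geometric length (parameter p) and residues drawn from pi,
and each branch evolves it independently under the model's conditional
transition probabilities at its branch time.  Unobservable double-deletion
runs are summed in closed form via the geometric factor
1/(1 - p t_DD t_DD).  The dynamic program is O(l1 x l2) in time and memory.

Local mode allows nonhomologous flanking regions (and, with reopening
probability r > 0, multiple homologous regions); q = r = 0 forces a global
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from . import _dp
from .evomodel import (B, D, FREE_PARAMETERS, I, M, TransitionSet, ancestral_p,
                       make_params, params_to_dict, reversibility_check,
                       transitions_at)
from .substitution import SubstitutionModel, blosum62_model


@dataclass
class EmissionParams:
    """Residue emission distributions of the composite model."""

    pi: np.ndarray  # ancestral residue distribution
    q_I: np.ndarray  # inserted-residue distribution
    subst: SubstitutionModel = None

    def __post_init__(self) -> None:
        for name, v in (("pi", self.pi), ("q_I", self.q_I)):
            if abs(float(np.sum(v)) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1")


@dataclass
class LocalFlankParams:
    """Flank model: geometric(q) nonhomologous stretches, r reopening."""

    q_flank: float = 0.0
    r_flank: float = 0.0
    f1: np.ndarray | None = None
    f2: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, v in (("q_flank", self.q_flank), ("r_flank", self.r_flank)):
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    @property
    def is_global(self) -> bool:
        return self.q_flank == 0.0 and self.r_flank == 0.0


@dataclass
class E2PairModel:
    """Everything needed to score two extant sequences."""

    model_id: str
    params: object
    t1: float
    t2: float
    subst: SubstitutionModel
    p: float
    emissions: EmissionParams
    flanks: LocalFlankParams
    trans1: TransitionSet = field(repr=False, default=None)
    trans2: TransitionSet = field(repr=False, default=None)
    P1: np.ndarray = field(repr=False, default=None)
    P2: np.ndarray = field(repr=False, default=None)

    @property
    def mode(self) -> str:
        return "global" if self.flanks.is_global else "local"

    @property
    def alphabet(self) -> str:
        return self.subst.alphabet


def build_model(model_id: str, params, t1: float, t2: float,
                subst: SubstitutionModel | None = None,
                emissions: EmissionParams | None = None,
                flanks: LocalFlankParams | None = None,
                p: float | None = None) -> E2PairModel:
    """Assemble an E2PairModel.

    ``p`` overrides the model's implied ancestral-length parameter (the
    tied value lam/mu_A for lr/afr, lam/mu for the TKF models); the
    transition functions are unaffected by the override.
    """
    subst = subst or blosum62_model()
    trans1 = transitions_at(model_id, params, t1)
    trans2 = transitions_at(model_id, params, t2)
    if p is None:
        p = ancestral_p(model_id, params)
    if not 0 <= p < 1:
        raise ValueError(f"ancestral length parameter p must be in [0, 1), got {p}")
    dd = p * trans1.t[D, D] * trans2.t[D, D]
    if dd >= 1.0:
        raise ValueError("p * t_DD * t_DD >= 1: double-deletion closure diverges")
    if emissions is None:
        emissions = EmissionParams(pi=subst.f, q_I=subst.f, subst=subst)
    if flanks is None:
        flanks = LocalFlankParams()
    return E2PairModel(model_id=model_id, params=params, t1=t1, t2=t2,
                       subst=subst, p=p, emissions=emissions, flanks=flanks,
                       trans1=trans1, trans2=trans2,
                       P1=subst.conditional_at(t1), P2=subst.conditional_at(t2))


# ---------------------------------------------------------------------------
# composite-state machinery


def _composite_arrays(model: E2PairModel):
    """Transition arrays over the 16 composite states for the DP kernels."""
    t1 = model.trans1.t
    t2 = model.trans2.t
    p = model.p
    amm = np.zeros(16)
    amd = np.zeros(16)
    adm = np.zeros(16)
    add = np.zeros(16)
    ins1w = np.zeros(16)
    ins2w = np.zeros(16)
    endw = np.zeros(16)
    for x1 in range(4):
        for x2 in range(4):
            s = 4 * x1 + x2
            amm[s] = p * t1[x1, M] * t2[x2, M]
            amd[s] = p * t1[x1, M] * t2[x2, D]
            adm[s] = p * t1[x1, D] * t2[x2, M]
            add[s] = p * t1[x1, D] * t2[x2, D]
            ins1w[s] = t1[x1, I]
            ins2w[s] = t2[x2, I]
            endw[s] = (1.0 - p) * (1.0 - t1[x1, I]) * (1.0 - t2[x2, I])
    return amm, amd, adm, add, ins1w, ins2w, endw


def encode(seq, alphabet: str) -> np.ndarray:
    """Encode a residue string (or int array) as an int array."""
    if isinstance(seq, str):
        try:
            return np.array([alphabet.index(c) for c in seq], dtype=np.int64)
        except ValueError as err:
            raise ValueError(f"sequence contains residues outside the model "
                             f"alphabet {alphabet!r}") from err
    seq = np.asarray(seq, dtype=np.int64)
    if seq.size and (seq.min() < 0 or seq.max() >= len(alphabet)):
        raise ValueError("encoded sequence indices outside the model alphabet")
    return seq


def _emission_arrays(x1: np.ndarray, x2: np.ndarray, model: E2PairModel):
    """Per-position emission arrays for two encoded sequences."""
    pi = model.emissions.pi
    qI = model.emissions.q_I
    # branch likelihood of each observed residue given each ancestor residue
    e1 = model.P1[:, x1]  # (K, l1)
    e2 = model.P2[:, x2]  # (K, l2)
    EMM = np.einsum("a,ai,aj->ij", pi, e1, e2)
    EM1 = pi @ e1
    EM2 = pi @ e2
    Q1 = qI[x1]
    Q2 = qI[x2]
    f1 = model.flanks.f1 if model.flanks.f1 is not None else model.subst.f
    f2 = model.flanks.f2 if model.flanks.f2 is not None else model.subst.f
    return (np.ascontiguousarray(EMM), EM1, EM2, Q1, Q2, f1[x1], f2[x2])


def e2_forward(s1, s2, model: E2PairModel) -> float:
    """log P(s1, s2 | model, t1, t2) in nats, summed over all histories."""
    x1 = encode(s1, model.alphabet)
    x2 = encode(s2, model.alphabet)
    arrays = _emission_arrays(x1, x2, model)
    trans = _composite_arrays(model)
    return float(_dp.e2_forward_kernel(
        *arrays, *trans, model.flanks.q_flank, model.flanks.r_flank))


@dataclass
class AlignmentResult:
    """A decoded alignment.

    ``columns`` is a list of (i, j, homologous) with 0-based residue
    indices (None for a gap); indices are strictly increasing per
    sequence.  ``score`` is the path log probability in nats.
    """

    columns: list
    score: float
    t_opt: float | None = None
    efficiency: float | None = None

    def aligned_pairs(self) -> set[tuple[int, int]]:
        """Residue index pairs placed in the same column."""
        return {(i, j) for i, j, _ in self.columns
                if i is not None and j is not None}

    def to_strings(self, s1: str, s2: str) -> tuple[str, str, str]:
        """Gapped alignment rows plus a homology annotation line."""
        r1, r2, hom = [], [], []
        for i, j, h in self.columns:
            r1.append(s1[i] if i is not None else "-")
            r2.append(s2[j] if j is not None else "-")
            hom.append("*" if h else ".")
        return "".join(r1), "".join(r2), "".join(hom)


def e2_forward_profiles(prof1: np.ndarray, prof2: np.ndarray,
                        model: E2PairModel) -> float:
    """Forward log probability for profile sequences.

    ``prof1``/``prof2`` are (l, K) per-position residue distributions
    instead of fixed residues (the generalization used when aligning
    inferred internal-node sequences); one-hot rows reduce exactly to
    plain sequences.
    """
    pi = model.emissions.pi
    qI = model.emissions.q_I
    e1 = model.P1 @ prof1.T  # (K, l1): E_b~prof [P(b|a)]
    e2 = model.P2 @ prof2.T
    EMM = np.einsum("a,ai,aj->ij", pi, e1, e2)
    EM1 = pi @ e1
    EM2 = pi @ e2
    Q1 = prof1 @ qI
    Q2 = prof2 @ qI
    f1 = model.flanks.f1 if model.flanks.f1 is not None else model.subst.f
    f2 = model.flanks.f2 if model.flanks.f2 is not None else model.subst.f
    arrays = (np.ascontiguousarray(EMM), EM1, EM2, Q1, Q2,
              prof1 @ f1, prof2 @ f2)
    trans = _composite_arrays(model)
    return float(_dp.e2_forward_kernel(
        *arrays, *trans, model.flanks.q_flank, model.flanks.r_flank))


def e2_viterbi(s1, s2, model: E2PairModel) -> AlignmentResult:
    """Maximum-probability history, decoded into aligned columns."""
    x1 = encode(s1, model.alphabet)
    x2 = encode(s2, model.alphabet)
    arrays = _emission_arrays(x1, x2, model)
    trans = _composite_arrays(model)
    l1, l2 = len(x1), len(x2)
    bp = np.full((l1 + 1, l2 + 1, _dp.NSTATE), -1, dtype=np.int16)
    score = float(_dp.e2_viterbi_kernel(
        *arrays, *trans, model.flanks.q_flank, model.flanks.r_flank, bp))
    if not np.isfinite(score):
        raise RuntimeError("no admissible alignment path (zero probability)")
    columns = _traceback(bp, l1, l2)
    return AlignmentResult(columns=columns, score=score)


def _traceback(bp: np.ndarray, l1: int, l2: int) -> list:
    A1, A2, C1, C2 = _dp.A1, _dp.A2, _dp.C1, _dp.C2
    MMs, MDs, DMs, DDs, BBs = _dp.MMs, _dp.MDs, _dp.DMs, _dp.DDs, _dp.BBs
    cols: list = []
    i, j, s = l1, l2, C2
    while True:
        pred = int(bp[i, j, s])
        if s == MMs:
            cols.append((i - 1, j - 1, True))
            i, j, s = i - 1, j - 1, pred
        elif s == MDs or 12 <= s <= 14:  # branch-1 match-vs-deletion or insert
            cols.append((i - 1, None, True))
            i, s = i - 1, pred
        elif s == DMs or (s < 16 and s % 4 == 3):  # branch-2 column
            cols.append((None, j - 1, True))
            j, s = j - 1, pred
        elif s == DDs or s == BBs:
            s = pred
        elif s == A1 or s == C1:
            if pred == _dp.START_BP:
                break
            if pred == s:  # flank emission
                cols.append((i - 1, None, False))
                i = i - 1
            else:  # reopening / closing a homologous region (same cell)
                s = pred
        elif s == A2 or s == C2:
            if pred == s:
                cols.append((None, j - 1, False))
                j = j - 1
            else:
                s = pred
        else:  # pragma: no cover - unreachable state
            raise RuntimeError(f"bad traceback state {s} at ({i}, {j})")
    cols.reverse()
    return cols


# ---------------------------------------------------------------------------
# plain ancestor/descendant pair HMM (reversible models only)


def _joint_transitions(model_id: str, params, t: float) -> TransitionSet:
    return transitions_at(model_id, params, t, mode="joint")


def _require_reversible(ts: TransitionSet) -> None:
    ok, viol = reversibility_check(ts)
    if not ok:
        raise ValueError(
            "a pair HMM aligns two extant sequences only under a reversible "
            f"model; joint chain breaks insert/delete symmetry by {viol:.3g}"
        )


def _pairhmm_tables(model_id: str, params, t: float,
                    subst: SubstitutionModel, q_I: np.ndarray | None):
    ts = _joint_transitions(model_id, params, t)
    _require_reversible(ts)
    T = ts.t
    end = ts.end_probabilities()
    P = subst.conditional_at(t)
    pi = subst.f
    qI = pi if q_I is None else q_I
    return T, end, pi[:, None] * P, pi, qI


def pairhmm_forward(s1, s2, model_id: str, params, t: float,
                    subst: SubstitutionModel | None = None,
                    q_I: np.ndarray | None = None) -> float:
    """Joint pair-HMM forward log probability of two extant sequences.

    Valid only for reversible models (afr/lr and degenerate cases); refuses
    nonreversible transition sets.
    """
    subst = subst or blosum62_model()
    T, end, JM, pi, qI = _pairhmm_tables(model_id, params, t, subst, q_I)
    x1 = encode(s1, subst.alphabet)
    x2 = encode(s2, subst.alphabet)
    l1, l2 = len(x1), len(x2)
    NEG = -np.inf
    V = np.full((l1 + 1, l2 + 1, 4), NEG)
    V[0, 0, B] = 0.0
    with np.errstate(divide="ignore"):
        logT = np.log(T)
        logend = np.log(end)
        logJM = np.log(JM)
        logpi = np.log(pi)
        logqI = np.log(qI)
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i > 0 and j > 0:
                V[i, j, M] = logJM[x1[i - 1], x2[j - 1]] + _lse(
                    V[i - 1, j - 1, :] + logT[:, M])
            if i > 0:
                V[i, j, D] = logpi[x1[i - 1]] + _lse(V[i - 1, j, :] + logT[:, D])
            if j > 0:
                V[i, j, I] = logqI[x2[j - 1]] + _lse(V[i, j - 1, :] + logT[:, I])
    return float(_lse(V[l1, l2, :] + logend))


def pairhmm_viterbi(s1, s2, model_id: str, params, t: float,
                    subst: SubstitutionModel | None = None,
                    q_I: np.ndarray | None = None) -> AlignmentResult:
    """Joint pair-HMM Viterbi alignment (reversible models only)."""
    subst = subst or blosum62_model()
    T, end, JM, pi, qI = _pairhmm_tables(model_id, params, t, subst, q_I)
    x1 = encode(s1, subst.alphabet)
    x2 = encode(s2, subst.alphabet)
    l1, l2 = len(x1), len(x2)
    V = np.full((l1 + 1, l2 + 1, 4), -np.inf)
    ptr = np.full((l1 + 1, l2 + 1, 4), -1, dtype=np.int8)
    V[0, 0, B] = 0.0
    with np.errstate(divide="ignore"):
        logT = np.log(T)
        logend = np.log(end)
        logJM = np.log(JM)
        logpi = np.log(pi)
        logqI = np.log(qI)
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i > 0 and j > 0:
                cand = V[i - 1, j - 1, :] + logT[:, M]
                ptr[i, j, M] = int(np.argmax(cand))
                V[i, j, M] = logJM[x1[i - 1], x2[j - 1]] + cand[ptr[i, j, M]]
            if i > 0:
                cand = V[i - 1, j, :] + logT[:, D]
                ptr[i, j, D] = int(np.argmax(cand))
                V[i, j, D] = logpi[x1[i - 1]] + cand[ptr[i, j, D]]
            if j > 0:
                cand = V[i, j - 1, :] + logT[:, I]
                ptr[i, j, I] = int(np.argmax(cand))
                V[i, j, I] = logqI[x2[j - 1]] + cand[ptr[i, j, I]]
    fin = V[l1, l2, :] + logend
    s = int(np.argmax(fin))
    score = float(fin[s])
    cols = []
    i, j = l1, l2
    while not (i == 0 and j == 0 and s == B):
        prev = int(ptr[i, j, s])
        if s == M:
            cols.append((i - 1, j - 1, True))
            i, j = i - 1, j - 1
        elif s == D:
            cols.append((i - 1, None, True))
            i -= 1
        elif s == I:
            cols.append((None, j - 1, True))
            j -= 1
        else:
            break
        s = prev
    cols.reverse()
    return AlignmentResult(columns=cols, score=score)


def _lse(v: np.ndarray) -> float:
    m = np.max(v)
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(v - m))))


# ---------------------------------------------------------------------------
# branch-length optimization, score efficiency, rate training


def _model_at_time(model: E2PairModel, t_total: float) -> E2PairModel:
    """Rebuild the model with branch times t_total/2 on each branch."""
    return build_model(model.model_id, model.params, t_total / 2.0,
                       t_total / 2.0, subst=model.subst,
                       emissions=model.emissions, flanks=model.flanks,
                       p=model.p)


def optimize_time(s1, s2, model: E2PairModel,
                  bounds: tuple[float, float] = (1e-3, 20.0),
                  xtol: float = 1e-4, n_starts: int = 3
                  ) -> tuple[float, float]:
    """Branch length maximizing the forward probability of a pair.

    One scalar t is optimized with t1 = t2 = t/2; the search is a bracketed
    scalar optimization on log t with multi-start against non-unimodal
    surfaces.  Returns (t_hat, log probability at t_hat); ties break toward
    smaller t.
    """
    x1 = encode(s1, model.alphabet)
    x2 = encode(s2, model.alphabet)

    def neg(u: float) -> float:
        return -e2_forward(x1, x2, _model_at_time(model, float(np.exp(u))))

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    best_u, best_val = None, np.inf
    edges = np.linspace(lo, hi, n_starts + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(neg, bounds=(a, b), method="bounded",
                              options={"xatol": xtol})
        better = res.fun < best_val - 1e-12
        tie = abs(res.fun - best_val) <= 1e-12 and (best_u is None or res.x < best_u)
        if best_u is None or better or tie:
            best_u, best_val = float(res.x), float(res.fun)
    # snap to the bracket edge when the optimum sits against it
    for edge in (lo, hi):
        if abs(best_u - edge) < 2 * xtol and neg(edge) <= best_val + 1e-12:
            best_u, best_val = edge, min(best_val, neg(edge))
    return float(np.exp(best_u)), -best_val


def null_score(s1, s2, model: E2PairModel) -> float:
    """log probability of two independent background sequences (nats)."""
    x1 = encode(s1, model.alphabet)
    x2 = encode(s2, model.alphabet)
    logf = np.log(model.subst.f)
    return float(logf[x1].sum() + logf[x2].sum())


def score_efficiency(s1, s2, fixed_t: float, model: E2PairModel,
                     t_opt: float | None = None) -> float:
    """Fraction of the maximal information captured at a fixed branch.

    The ratio of the log-odds forward score (forward minus the
    independent-sequences null) at the fixed branch length to the score at
    the optimal branch length; <= 1 up to optimizer tolerance when both
    scores are positive.
    """
    if t_opt is None:
        t_opt, opt_fwd = optimize_time(s1, s2, model)
    else:
        opt_fwd = e2_forward(s1, s2, _model_at_time(model, t_opt))
    null = null_score(s1, s2, model)
    fixed_fwd = e2_forward(s1, s2, _model_at_time(model, fixed_t))
    return (fixed_fwd - null) / (opt_fwd - null)


_RATE_PARAMS = {"lam", "mu", "muA", "muA_M", "muA_D", "muA_I"}
# everything else (fragment/burst Bernoullis, s_I, p) lives in [0, 1)


def fit_rates(pairs, model_id: str, init: dict, t: float | np.ndarray,
              subst: SubstitutionModel | None = None,
              p: float | None = None, fixed: tuple[str, ...] = ("p",),
              maxiter: int = 60) -> tuple[dict, float]:
    """Maximum-likelihood rates for a model family from training pairs.

    Maximizes sum of e2_forward log probabilities over ``pairs`` (sequence
    tuples) by quasi-Newton ascent with numerical gradients on transformed
    parameters (log for rates, logit for Bernoulli parameters).  ``t`` is
    the total divergence per pair (scalar or array); ``p`` fixes the
    ancestral-length parameter (default: matched to the mean sequence
    length of the data, which keeps length modeling from leaking into the
    rate estimates).  Returns (fitted params dict, total log probability).
    Deterministic given the initial values.
    """
    subst = subst or blosum62_model()
    names = [n for n in FREE_PARAMETERS[model_id.lower()] if n not in fixed]
    enc_pairs = [(encode(a, subst.alphabet), encode(b, subst.alphabet))
                 for a, b in pairs]
    times = np.broadcast_to(np.asarray(t, dtype=float), (len(enc_pairs),))
    if p is None:
        mean_len = float(np.mean([(len(a) + len(b)) / 2 for a, b in enc_pairs]))
        p = mean_len / (1.0 + mean_len)

    def transform(vals: dict) -> np.ndarray:
        out = []
        for n in names:
            v = vals[n]
            out.append(np.log(v) if n in _RATE_PARAMS
                       else np.log(v / (1.0 - v)))
        return np.array(out)

    def untransform(x: np.ndarray) -> dict:
        vals = dict(init)
        for n, u in zip(names, x):
            vals[n] = float(np.exp(u)) if n in _RATE_PARAMS \
                else float(1.0 / (1.0 + np.exp(-u)))
        return vals

    # emissions depend on the substitution model and times only, not on
    # the indel rates being fitted: precompute them once per pair
    base = build_model(model_id, make_params(model_id, **init),
                       times[0] / 2, times[0] / 2, subst=subst, p=p)
    cached = []
    for (a, b), tt in zip(enc_pairs, times):
        m = base if tt == times[0] else build_model(
            model_id, base.params, tt / 2, tt / 2, subst=subst, p=p)
        cached.append(_emission_arrays(a, b, m))

    def negloglik(x: np.ndarray) -> float:
        vals = untransform(x)
        try:
            params = make_params(model_id, **vals)
        except ValueError:
            return 1e12
        total = 0.0
        trans_cache: dict[float, tuple] = {}
        for arrays, tt in zip(cached, times):
            tr = trans_cache.get(tt)
            if tr is None:
                model = build_model(model_id, params, tt / 2, tt / 2,
                                    subst=subst, p=p)
                tr = _composite_arrays(model)
                trans_cache[tt] = tr
            total += float(_dp.e2_forward_kernel(*arrays, *tr, 0.0, 0.0))
        return -total

    x0 = transform(init)
    res = minimize(negloglik, x0, method="L-BFGS-B",
                   options={"maxiter": maxiter, "eps": 1e-3})
    best_x = res.x if res.fun <= negloglik(x0) else x0
    fitted = untransform(best_x)
    fitted["p"] = p
    return fitted, -float(min(res.fun, negloglik(x0)))
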