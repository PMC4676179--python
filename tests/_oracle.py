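"""Independent oracles for the common-ancestor alignment engine.

Three layered routes, all independent of the production DP kernel:

* ``branch_histories`` enumerates one branch's event strings explicitly;
* ``oracle_forward`` sums over all ancestral sequences (explicit
  enumeration up to a length bound with a certified tail bound) with a
  straightforward per-ancestor conditional forward;
* ``oracle_history_scores`` enumerates composite histories (pairs of
  branch event strings) for the smallest cases, giving both the summed
  (forward) and the maximal (Viterbi) history weight.

``oracle_local_forward`` composes global-oracle values over all
flank/core segmentations of the local model.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from e2align.evomodel import B, D, I, M


def branch_histories(l_desc: int, L_anc: int):
    """All event strings over M/D/I with #M+#D = L_anc, #M+#I = l_desc."""
    out = []

    def rec(prefix, n_anc, n_desc):
        if n_anc == L_anc and n_desc == l_desc:
            out.append("".join(prefix))
            return
        if n_anc < L_anc:
            prefix.append("D")
            rec(prefix, n_anc + 1, n_desc)
            prefix.pop()
            if n_desc < l_desc:
                prefix.append("M")
                rec(prefix, n_anc + 1, n_desc + 1)
                prefix.pop()
        if n_desc < l_desc:
            prefix.append("I")
            rec(prefix, n_anc, n_desc + 1)
            prefix.pop()
    rec([], 0, 0)
    return out


def branch_history_weight(events: str, t: np.ndarray) -> float:
    """Transition weight of one branch event string (emissions excluded).

    Includes the end factor (1 - t[last, I]); the chain starts in B.
    """
    idx = {"M": M, "D": D, "I": I}
    w = 1.0
    st = B
    for e in events:
        w *= t[st, idx[e]]
        st = idx[e]
    return w * (1.0 - t[st, I])


def branch_conditional_forward(x: np.ndarray, ancestors: np.ndarray,
                               t: np.ndarray, P: np.ndarray,
                               qI: np.ndarray) -> np.ndarray:
    """P(descendant x | ancestor) for a batch of ancestors, by simple DP.

    ``ancestors`` is (nA, L) encoded; returns (nA,) probabilities.  The DP
    iterates ancestral positions, with insert chains along the descendant
    between them -- organized differently from the production kernel.
    """
    nA, L = ancestors.shape
    l = len(x)
    V = np.zeros((nA, l + 1, 4))
    V[:, 0, B] = 1.0

    def insert_chain(V):
        for i in range(1, l + 1):
            V[:, i, I] += (V[:, i - 1, :] @ t[:, I]) * qI[x[i - 1]]

    insert_chain(V)
    for k in range(L):
        new = np.zeros_like(V)
        for i in range(l + 1):
            if i >= 1:
                new[:, i, M] = (V[:, i - 1, :] @ t[:, M]) \
                    * P[ancestors[:, k], x[i - 1]]
            new[:, i, D] = V[:, i, :] @ t[:, D]
        insert_chain(new)
        V = new
    return V[:, l, :] @ (1.0 - t[:, I])


def oracle_forward(x1: np.ndarray, x2: np.ndarray, K: int, p: float,
                   pi: np.ndarray, t1: np.ndarray, t2: np.ndarray,
                   P1: np.ndarray, P2: np.ndarray, qI: np.ndarray,
                   tol: float = 1e-13) -> float:
    """Forward probability by explicit enumeration over ancestors.

    Sums (1-p) p^L sum_{a in K^L} prod pi(a) P(x1|a) P(x2|a), increasing L
    until the certified tail bound falls below ``tol`` times the running
    total: beyond max(l1, l2), each extra ancestral position contributes at
    most a factor p * max t1[., D] * max t2[., D].  Returns log probability.
    """
    total = 0.0
    lmax = max(len(x1), len(x2))
    g = p * t1[:, D].max() * t2[:, D].max()
    L = 0
    while True:
        if L == 0:
            ancestors = np.zeros((1, 0), dtype=np.int64)
            w = np.ones(1)
        else:
            ancestors = np.array(list(product(range(K), repeat=L)),
                                 dtype=np.int64)
            w = np.prod(pi[ancestors], axis=1)
        F1 = branch_conditional_forward(x1, ancestors, t1, P1, qI)
        F2 = branch_conditional_forward(x2, ancestors, t2, P2, qI)
        total += (1.0 - p) * p ** L * float(w @ (F1 * F2))
        if L >= lmax and g < 1.0:
            tail = (1.0 - p) * p ** lmax * g ** (L + 1 - lmax) / (1.0 - g)
            if tail < tol * max(total, 1e-300):
                break
        if L > 30:
            raise RuntimeError("oracle did not converge by L = 30")
        L += 1
    return float(np.log(total))


def _consumed_indices(ev: str):
    out = []
    i = 0
    for e in ev:
        if e in "MI":
            out.append(i)
            i += 1
        else:
            out.append(None)
    return out


def composite_history_weight(L: int, ev1: str, ev2: str, p: float,
                             t1: np.ndarray, t2: np.ndarray,
                             e1m: np.ndarray, e2m: np.ndarray,
                             EMM: np.ndarray, q1: np.ndarray,
                             q2: np.ndarray, x1: np.ndarray,
                             x2: np.ndarray) -> float:
    """Weight of one composite history (ancestor residues marginalized)."""
    w = (1.0 - p) * p ** L
    w *= branch_history_weight(ev1, t1) * branch_history_weight(ev2, t2)
    c1 = _consumed_indices(ev1)
    c2 = _consumed_indices(ev2)
    fates1 = [(e, c1[i]) for i, e in enumerate(ev1) if e in "MD"]
    fates2 = [(e, c2[j]) for j, e in enumerate(ev2) if e in "MD"]
    for (e1, i), (e2, j) in zip(fates1, fates2):
        if e1 == "M" and e2 == "M":
            w *= EMM[x1[i], x2[j]]
        elif e1 == "M":
            w *= e1m[x1[i]]
        elif e2 == "M":
            w *= e2m[x2[j]]
    for idx, e in enumerate(ev1):
        if e == "I":
            w *= q1[x1[c1[idx]]]
    for idx, e in enumerate(ev2):
        if e == "I":
            w *= q2[x2[c2[idx]]]
    return w


def oracle_history_scores(x1, x2, p, pi, t1, t2, P1, P2, qI,
                          Lmax: int | None = None):
    """(log sum, log max) over explicitly enumerated composite histories."""
    if Lmax is None:
        Lmax = len(x1) + len(x2) + 8
    EMM = np.einsum("a,ab,ac->bc", pi, P1, P2)
    e1m = pi @ P1
    e2m = pi @ P2
    total = 0.0
    best = 0.0
    for L in range(Lmax + 1):
        for ev1 in branch_histories(len(x1), L):
            for ev2 in branch_histories(len(x2), L):
                w = composite_history_weight(L, ev1, ev2, p, t1, t2,
                                             e1m, e2m, EMM, qI, qI, x1, x2)
                total += w
                best = max(best, w)
    return float(np.log(total)), float(np.log(best))


def oracle_local_forward(x1, x2, K, p, pi, t1, t2, P1, P2, qI,
                         q: float, r: float, f1: np.ndarray,
                         f2: np.ndarray) -> float:
    """Local-mode forward by segmenting over flanks and global cores.

    The local structure is [flank1 flank2 core] x n (n >= 1, reopening
    weight r per extra region) followed by trailing flanks.  Cores are
    scored with the global ancestor-enumeration oracle on substrings.
    Zero-growth blocks (both flanks empty, empty core) recur at the same
    cell and are summed as a geometric series.
    """
    l1, l2 = len(x1), len(x2)
    core = {}
    for i1 in range(l1 + 1):
        for i2 in range(i1, l1 + 1):
            for j1 in range(l2 + 1):
                for j2 in range(j1, l2 + 1):
                    core[(i1, i2, j1, j2)] = np.exp(oracle_forward(
                        x1[i1:i2], x2[j1:j2], K, p, pi, t1, t2, P1, P2, qI))

    def flank_w(x, f, a, b):
        w = 1.0 - q
        for k in range(a, b):
            w *= q * f[x[k]]
        return w

    z_empty = (1.0 - q) ** 2
    done = np.zeros((l1 + 1, l2 + 1))  # mass ending right after a core
    acc = np.zeros((l1 + 1, l2 + 1))  # contributions from smaller cells
    first = np.zeros((l1 + 1, l2 + 1))
    first[0, 0] = 1.0
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            block0 = z_empty * core[(i, i, j, j)]
            done[i, j] = (acc[i, j] + first[i, j] * block0) \
                / (1.0 - r * block0)
            # the first block may also grow; route start mass like reopen
            src = first[i, j] + r * done[i, j]
            for a in range(i, l1 + 1):
                for b in range(j, l2 + 1):
                    fw = flank_w(x1, f1, i, a) * flank_w(x2, f2, j, b)
                    for c in range(a, l1 + 1):
                        for d_ in range(b, l2 + 1):
                            if (c, d_) == (i, j):
                                continue  # zero growth in the closure
                            acc[c, d_] += src * fw * core[(a, c, b, d_)]
    total = 0.0
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            total += done[i, j] * (1.0 - r) \
                * flank_w(x1, f1, i, l1) * flank_w(x2, f2, j, l2)
    return float(np.log(total))
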