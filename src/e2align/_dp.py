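"""Numba dynamic-programming kernels for the common-ancestor pair model.

The composite state space is the product of the two branches' pair-HMM
states, s = 4*x1 + x2 with x in {B=0, M=1, D=2, I=3}:

* advances (both branches take an ancestral fate in {M, D}) move
  (i-1,j-1) for (M,M), (i-1,j) for (M,D), (i,j-1) for (D,M) and stay in
  the same cell for the non-emitting (D,D);
* branch-1 inserts move (i-1,j) into states (I, x2), branch-2 inserts move
  (i,j-1) into (x1, I).  Interleavings are canonicalized (branch-1 inserts
  precede branch-2 inserts between ancestral positions) by forbidding
  branch-1 inserts once x2 = I, which makes the grammar unambiguous.

Local mode wraps the core in four flank states (A1/A2 before or between
homologous regions, C1/C2 trailing), each emitting geometric(q) stretches
of background residues; the expected number of extra homologous regions is
r/(1-r).  q = r = 0 is exactly the global model.

Non-emitting transitions within a cell (A1->A2->BB, advance into DD, core
end -> A1/C1) form convergent geometric cycles; the kernels solve the
per-cell linear system in closed form (forward) or relax it twice (Viterbi,
where cycles are never optimal because every cycle weight is < 1).

All DP is in linear space with per-row rescaling; the returned value is
log(probability) in nats.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NSTATE = 20
A1, A2, C1, C2 = 16, 17, 18, 19
BBs, MMs, MDs, DMs, DDs = 0, 5, 6, 9, 10
START_BP = 100  # backpointer code for the start of the path

_RESCALE_BELOW = 1e-60


@njit(cache=True)
def _close_cell_forward(cur, j, add, endw, q, r, a1e, a2e, c1e, c2e, init):
    """Solve the same-cell non-emitting system; writes BB, DD, A1, A2, C1, C2."""
    S0e = 0.0
    D0 = 0.0
    for s in range(16):
        if s == BBs or s == DDs:
            continue
        v = cur[j, s]
        S0e += v * endw[s]
        D0 += v * add[s]
    g = 1.0 / (1.0 - add[DDs])
    c0 = S0e + D0 * g * endw[DDs]
    ccoef = endw[BBs] + add[BBs] * g * endw[DDs]
    k = (1.0 - q) * (1.0 - q)
    denom = 1.0 - k * r * ccoef
    bb = ((1.0 - q) * a2e + k * (a1e + init) + k * r * c0) / denom
    dd = (D0 + bb * add[BBs]) * g
    CE = S0e + bb * endw[BBs] + dd * endw[DDs]
    a1 = a1e + init + r * CE
    a2 = a2e + (1.0 - q) * a1
    cur[j, BBs] = bb
    cur[j, DDs] = dd
    cur[j, A1] = a1
    cur[j, A2] = a2
    cur[j, C1] = c1e + (1.0 - r) * CE
    cur[j, C2] = c2e + (1.0 - q) * cur[j, C1]


@njit(cache=True)
def e2_forward_kernel(EMM, EM1, EM2, Q1, Q2, FL1, FL2,
                      amm, amd, adm, add, ins1w, ins2w, endw,
                      q, r):
    """Forward log-probability of two sequences under the composite model.

    EMM is (l1, l2) joint match emissions; EM1/EM2 are half-match (one
    branch deleted) emissions; Q1/Q2 insert emissions; FL1/FL2 flank
    emissions -- all per position.  The transition arrays are indexed by
    composite state.
    """
    l1 = EM1.shape[0]
    l2 = EM2.shape[0]
    prev = np.zeros((l2 + 1, NSTATE))
    cur = np.zeros((l2 + 1, NSTATE))
    logscale = 0.0
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            for s in range(NSTATE):
                cur[j, s] = 0.0
            # emitting core entries
            if i >= 1 and j >= 1:
                acc = 0.0
                for s in range(16):
                    acc += prev[j - 1, s] * amm[s]
                cur[j, MMs] = acc * EMM[i - 1, j - 1]
            if i >= 1:
                acc = 0.0
                for s in range(16):
                    acc += prev[j, s] * amd[s]
                cur[j, MDs] = acc * EM1[i - 1]
                # branch-1 inserts into (I, x2), x2 != I
                for x2 in range(3):
                    acc = 0.0
                    for x1 in range(4):
                        s = 4 * x1 + x2
                        acc += prev[j, s] * ins1w[s]
                    cur[j, 12 + x2] = acc * Q1[i - 1]
            if j >= 1:
                acc = 0.0
                for s in range(16):
                    acc += cur[j - 1, s] * adm[s]
                cur[j, DMs] = acc * EM2[j - 1]
                # branch-2 inserts into (x1, I)
                for x1 in range(4):
                    acc = 0.0
                    for x2 in range(4):
                        s = 4 * x1 + x2
                        acc += cur[j - 1, s] * ins2w[s]
                    cur[j, 4 * x1 + 3] = acc * Q2[j - 1]
            a1e = prev[j, A1] * q * FL1[i - 1] if i >= 1 else 0.0
            a2e = cur[j - 1, A2] * q * FL2[j - 1] if j >= 1 else 0.0
            c1e = prev[j, C1] * q * FL1[i - 1] if i >= 1 else 0.0
            c2e = cur[j - 1, C2] * q * FL2[j - 1] if j >= 1 else 0.0
            init = 1.0 if (i == 0 and j == 0) else 0.0
            _close_cell_forward(cur, j, add, endw, q, r, a1e, a2e, c1e, c2e, init)
        m = 0.0
        for j in range(l2 + 1):
            for s in range(NSTATE):
                if cur[j, s] > m:
                    m = cur[j, s]
        if m > 0.0 and m < _RESCALE_BELOW:
            inv = 1.0 / m
            for j in range(l2 + 1):
                for s in range(NSTATE):
                    cur[j, s] *= inv
            logscale += np.log(m)
        tmp = prev
        prev = cur
        cur = tmp
    total = prev[l2, C2] * (1.0 - q)
    if total <= 0.0:
        return -np.inf
    return np.log(total) + logscale


@njit(cache=True)
def e2_viterbi_kernel(EMM, EM1, EM2, Q1, Q2, FL1, FL2,
                      amm, amd, adm, add, ins1w, ins2w, endw,
                      q, r, bp):
    """Viterbi variant; fills backpointers bp (l1+1, l2+1, NSTATE) int16.

    bp[i, j, s] is the predecessor composite state; the move geometry is
    implied by s (see traceback in e2pair).  Returns the Viterbi log
    probability.
    """
    l1 = EM1.shape[0]
    l2 = EM2.shape[0]
    prev = np.zeros((l2 + 1, NSTATE))
    cur = np.zeros((l2 + 1, NSTATE))
    logscale = 0.0
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            for s in range(NSTATE):
                cur[j, s] = 0.0
                bp[i, j, s] = -1
            if i >= 1 and j >= 1:
                best = 0.0
                barg = -1
                for s in range(16):
                    v = prev[j - 1, s] * amm[s]
                    if v > best:
                        best = v
                        barg = s
                cur[j, MMs] = best * EMM[i - 1, j - 1]
                bp[i, j, MMs] = barg
            if i >= 1:
                best = 0.0
                barg = -1
                for s in range(16):
                    v = prev[j, s] * amd[s]
                    if v > best:
                        best = v
                        barg = s
                cur[j, MDs] = best * EM1[i - 1]
                bp[i, j, MDs] = barg
                for x2 in range(3):
                    best = 0.0
                    barg = -1
                    for x1 in range(4):
                        s = 4 * x1 + x2
                        v = prev[j, s] * ins1w[s]
                        if v > best:
                            best = v
                            barg = s
                    cur[j, 12 + x2] = best * Q1[i - 1]
                    bp[i, j, 12 + x2] = barg
            if j >= 1:
                best = 0.0
                barg = -1
                for s in range(16):
                    v = cur[j - 1, s] * adm[s]
                    if v > best:
                        best = v
                        barg = s
                cur[j, DMs] = best * EM2[j - 1]
                bp[i, j, DMs] = barg
                for x1 in range(4):
                    best = 0.0
                    barg = -1
                    for x2 in range(4):
                        s = 4 * x1 + x2
                        v = cur[j - 1, s] * ins2w[s]
                        if v > best:
                            best = v
                            barg = s
                    cur[j, 4 * x1 + 3] = best * Q2[j - 1]
                    bp[i, j, 4 * x1 + 3] = barg
            a1e = prev[j, A1] * q * FL1[i - 1] if i >= 1 else 0.0
            a2e = cur[j - 1, A2] * q * FL2[j - 1] if j >= 1 else 0.0
            c1e = prev[j, C1] * q * FL1[i - 1] if i >= 1 else 0.0
            c2e = cur[j - 1, C2] * q * FL2[j - 1] if j >= 1 else 0.0
            init = 1.0 if (i == 0 and j == 0) else 0.0
            # relax the same-cell non-emitting system twice; cycles have
            # weight < 1 so an optimal path traverses each link at most once
            for _ in range(2):
                bestCE = 0.0
                argCE = -1
                for s in range(16):
                    v = cur[j, s] * endw[s]
                    if v > bestCE:
                        bestCE = v
                        argCE = s
                # A1: from up-emission, start, or reopening after a region
                best = a1e
                barg = A1
                if init > best:
                    best = init
                    barg = START_BP
                if r * bestCE > best:
                    best = r * bestCE
                    barg = argCE
                if best > cur[j, A1]:
                    cur[j, A1] = best
                    bp[i, j, A1] = barg
                # A2
                best = a2e
                barg = A2
                v = (1.0 - q) * cur[j, A1]
                if v > best:
                    best = v
                    barg = A1
                if best > cur[j, A2]:
                    cur[j, A2] = best
                    bp[i, j, A2] = barg
                # BB
                v = (1.0 - q) * cur[j, A2]
                if v > cur[j, BBs]:
                    cur[j, BBs] = v
                    bp[i, j, BBs] = A2
                # DD (self-loop never optimal)
                best = 0.0
                barg = -1
                for s in range(16):
                    if s == DDs:
                        continue
                    v = cur[j, s] * add[s]
                    if v > best:
                        best = v
                        barg = s
                if best > cur[j, DDs]:
                    cur[j, DDs] = best
                    bp[i, j, DDs] = barg
                # C1
                best = c1e
                barg = C1
                v = (1.0 - r) * bestCE
                if v > best:
                    best = v
                    barg = argCE
                if best > cur[j, C1]:
                    cur[j, C1] = best
                    bp[i, j, C1] = barg
                # C2
                best = c2e
                barg = C2
                v = (1.0 - q) * cur[j, C1]
                if v > best:
                    best = v
                    barg = C1
                if best > cur[j, C2]:
                    cur[j, C2] = best
                    bp[i, j, C2] = barg
        m = 0.0
        for j in range(l2 + 1):
            for s in range(NSTATE):
                if cur[j, s] > m:
                    m = cur[j, s]
        if m > 0.0 and m < _RESCALE_BELOW:
            inv = 1.0 / m
            for j in range(l2 + 1):
                for s in range(NSTATE):
                    cur[j, s] *= inv
            logscale += np.log(m)
        tmp = prev
        prev = cur
        cur = tmp
    total = prev[l2, C2] * (1.0 - q)
    if total <= 0.0:
        return -np.inf
    return np.log(total) + logscale
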