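"""Microscopic indel-evolution simulator and sampling utilities.

The simulator implements the GM (Geometric) family of junction processes.
Every junction between two remembered ancestral positions carries an
"insert": the collection of all residues inserted there, alive ancestors or
not.  Events at a junction holding n residues:

* opening channel, rate lam (always active): a geometric(v_I) burst of
  residues appears next to the junction anchor;
* expansion, rate lamI per resident residue: another geometric(v_I) burst;
* emptying channel, rate mu (active when n >= 1): removes a geometric(v_D)
  burst, possibly the whole insert;
* shrinkage, rate muI per residue beyond the first: removes a
  geometric(v_D) burst capped so the insert does not empty.

With lam = lamI, mu = muI and v_I = v_D = 0 (the aali special case) the
junction reduces exactly to the immortal-link linear birth-death chain
(birth (n+1) lam, death n mu), whose insert length is geometrically
distributed at every time -- the only member of the family compatible with
affine gap costs.  Unequal open/extend rates or geometric bursts leave the
affine world, which is what the goodness-of-fit machinery demonstrates.

Ancestral residues are deleted with a context-dependent rate mu_A^X where X
is the current state of the immediately preceding element: I if the
adjacent insert is nonempty, else D if the preceding ancestral position is
dead, else M (with mu_A^B = mu_A^M for the first position).

Everything is exact event-driven (Gillespie) simulation by default; a
discretized dt mode is provided for fidelity to infinitesimal-step
sampling and cross-checked against the exact engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .evomodel import (GMParams, SingleResidueParams, ancestral_p,
                       transitions_at)
from .substitution import SubstitutionModel


@dataclass
class SimulationConfig:
    """Scale and engine settings for a simulation run."""

    n_ancestors: int = 100
    ancestor_len: int = 1000
    t_end: float = 1.0
    dt: float = 1e-5
    engine: str = "gillespie"  # or "discretized"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.engine not in ("gillespie", "discretized"):
            raise ValueError(f"unknown engine {self.engine!r}")


def _gm_params(params) -> GMParams:
    if isinstance(params, GMParams):
        return params
    if isinstance(params, SingleResidueParams):
        return GMParams(lam=params.lam, lamI=params.lam, mu=params.mu,
                        muI=params.mu, vI=0.0, vD=0.0)
    raise TypeError(f"cannot simulate parameters of type {type(params)!r}")


def _muA(params) -> tuple[float, float, float]:
    if isinstance(params, SingleResidueParams):
        return params.muA_M, params.muA_D, params.muA_I
    return 0.0, 0.0, 0.0


def _burst(rng: np.random.Generator, v: float) -> int:
    """Geometric(v) burst size, support >= 1."""
    if v == 0.0:
        return 1
    return int(rng.geometric(1.0 - v))


def simulate_junction(gm: GMParams, t_end: float, rng: np.random.Generator,
                      max_events: int = 1_000_000
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Exact trajectory of one junction's insert length.

    Returns (times, lengths): event times (starting at 0) and the insert
    length after each, with lengths[0] = 0.
    """
    times = [0.0]
    ns = [0]
    t, n = 0.0, 0
    warned = 0
    while True:
        open_rate = gm.lam
        expand = n * gm.lamI
        empty = gm.mu if n >= 1 else 0.0
        shrink = max(n - 1, 0) * gm.muI
        total = open_rate + expand + empty + shrink
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = rng.random() * total
        if u < open_rate + expand:
            n += _burst(rng, gm.vI)
        elif u < open_rate + expand + empty:
            n = max(n - _burst(rng, gm.vD), 0)
        else:
            n = max(n - min(_burst(rng, gm.vD), n - 1), 1)
        times.append(t)
        ns.append(n)
        warned += 1
        if warned >= max_events:
            raise RuntimeError("junction simulation exceeded max_events")
    return np.array(times), np.array(ns, dtype=np.int64)


def simulate_junction_discretized(gm: GMParams, t_end: float, dt: float,
                                  rng: np.random.Generator
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Infinitesimal-step trajectory: each channel fires with prob rate*dt."""
    n = 0
    times = [0.0]
    ns = [0]
    steps = int(np.ceil(t_end / dt))
    # thinning: draw candidate event steps from the maximal per-step
    # probability, then accept against the state-dependent rates
    k = 0
    while k < steps:
        birth = gm.lam + n * gm.lamI
        death = (gm.mu if n >= 1 else 0.0) + max(n - 1, 0) * gm.muI
        total = (birth + death) * dt
        if total <= 0.0:
            break
        # geometric skip to the next step with any firing
        skip = int(rng.geometric(min(total, 1.0)))
        k += skip
        if k > steps:
            break
        u = rng.random() * (birth + death)
        if u < birth:
            n += _burst(rng, gm.vI)
        elif u < birth + (gm.mu if n >= 1 else 0.0):
            n = max(n - _burst(rng, gm.vD), 0)
        else:
            n = max(n - min(_burst(rng, gm.vD), n - 1), 1)
        times.append(k * dt)
        ns.append(n)
    return np.array(times), np.array(ns, dtype=np.int64)


@dataclass
class InsertRecord:
    """Per-ancestor junction insert lengths and survival flags at t_end."""

    insert_lengths: np.ndarray  # (L + 1,) residues at each junction
    survived: np.ndarray  # (L,) ancestral survival flags
    death_times: np.ndarray  # (L,) np.inf for survivors


@dataclass
class SegmentTallies:
    """Constant-context exposure segments for elementary-function checks.

    For each context state X in {M, D, I}, ``durations[X]`` holds exposure
    lengths of maximal constant-context intervals entered alive, and
    ``died[X]`` whether the position died within that interval.  Under the
    model, death within an interval of length d is Bernoulli with
    probability 1 - exp(-mu_A^X d).
    """

    durations: dict = field(default_factory=lambda: {"M": [], "D": [], "I": []})
    died: dict = field(default_factory=lambda: {"M": [], "D": [], "I": []})


def _context_segments(times: np.ndarray, ns: np.ndarray, prev_death: float,
                      t_end: float) -> list[tuple[str, float, float]]:
    """Maximal constant-context intervals [a, b) for one position."""
    # breakpoints: junction occupancy changes and the predecessor's death
    points = [0.0, t_end]
    points.extend(tt for tt in times if 0.0 < tt < t_end)
    if 0.0 < prev_death < t_end:
        points.append(prev_death)
    points = sorted(set(points))
    segs = []
    for a, b in zip(points[:-1], points[1:]):
        k = int(np.searchsorted(times, a, side="right")) - 1
        occupied = ns[k] > 0
        if occupied:
            state = "I"
        elif a >= prev_death:
            state = "D"
        else:
            state = "M"
        if segs and segs[-1][0] == state:
            segs[-1] = (state, segs[-1][1], b)
        else:
            segs.append((state, a, b))
    return segs


def _sample_death(segs, muA_M: float, muA_D: float, muA_I: float,
                  rng: np.random.Generator,
                  tallies: SegmentTallies | None) -> float:
    """Death time of one position under piecewise-constant context hazard."""
    rate = {"M": muA_M, "D": muA_D, "I": muA_I}
    budget = rng.exponential(1.0)
    acc = 0.0
    death = np.inf
    for state, a, b in segs:
        r = rate[state]
        seg_death = np.inf
        if r > 0 and acc + r * (b - a) >= budget and death == np.inf:
            seg_death = a + (budget - acc) / r
        if death == np.inf and tallies is not None:
            tallies.durations[state].append(b - a)
            tallies.died[state].append(seg_death < np.inf)
        if seg_death < np.inf and death == np.inf:
            death = seg_death
        acc += r * (b - a)
    return death


def evolve(config: SimulationConfig, params,
           tallies: SegmentTallies | None = None) -> list[InsertRecord]:
    """Evolve N ancestors of length L to t_end; returns per-ancestor records.

    ``params`` is GMParams (pure junction dynamics, no ancestral deaths) or
    SingleResidueParams (aali family: junction dynamics with lam = lamI,
    mu = muI plus context-dependent ancestral deletion).  Pass a
    SegmentTallies to collect constant-context death statistics.
    """
    gm = _gm_params(params)
    muA_M, muA_D, muA_I = _muA(params)
    rng = np.random.default_rng(config.seed)
    records = []
    for _ in range(config.n_ancestors):
        L = config.ancestor_len
        lengths = np.zeros(L + 1, dtype=np.int64)
        death_times = np.full(L, np.inf)
        prev_death = np.inf
        for x in range(L):
            if config.engine == "gillespie":
                times, ns = simulate_junction(gm, config.t_end, rng)
            else:
                times, ns = simulate_junction_discretized(
                    gm, config.t_end, config.dt, rng)
            lengths[x] = ns[-1]
            if muA_M or muA_D or muA_I:
                segs = _context_segments(times, ns, prev_death, config.t_end)
                death_times[x] = _sample_death(segs, muA_M, muA_D, muA_I,
                                               rng, tallies)
            prev_death = death_times[x]
        if config.engine == "gillespie":
            times, ns = simulate_junction(gm, config.t_end, rng)
        else:
            times, ns = simulate_junction_discretized(gm, config.t_end,
                                                      config.dt, rng)
        lengths[L] = ns[-1]
        records.append(InsertRecord(insert_lengths=lengths,
                                    survived=np.isinf(death_times),
                                    death_times=death_times))
    return records


def insert_lengths(records: list[InsertRecord]) -> np.ndarray:
    """Pooled junction insert lengths across ancestors."""
    return np.concatenate([r.insert_lengths for r in records])


def geometric_fit(lengths) -> dict:
    """ML geometric fit q^l (1-q) on support l >= 0, with G and chi2 tests.

    Expected counts below 5 are pooled into the tail; degrees of freedom
    are bins - 2 (one fitted parameter).  Returns a dict with q_hat, G,
    chi2, dof and the two p-values.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("geometric_fit requires at least one length")
    if np.any(lengths < 0):
        raise ValueError("lengths must be nonnegative integers")
    n = lengths.size
    mean = lengths.mean()
    q = mean / (1.0 + mean)
    if q == 0.0:
        return {"q_hat": 0.0, "G": 0.0, "chi2": 0.0, "dof": 0,
                "p_G": 1.0, "p_chi2": 1.0}
    lmax = int(lengths.max())
    observed = np.bincount(lengths, minlength=lmax + 1).astype(float)
    probs = (1.0 - q) * q ** np.arange(lmax + 1)
    probs = np.append(probs, q ** (lmax + 1))  # tail mass
    observed = np.append(observed, 0.0)
    expected = n * probs
    # pool from the tail until every bin expects >= 5
    obs_bins, exp_bins = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed[::-1], expected[::-1]):
        o_acc += o
        e_acc += e
        if e_acc >= 5.0:
            obs_bins.append(o_acc)
            exp_bins.append(e_acc)
            o_acc = e_acc = 0.0
    if obs_bins and (o_acc or e_acc):
        obs_bins[-1] += o_acc
        exp_bins[-1] += e_acc
    obs = np.array(obs_bins[::-1])
    exp = np.array(exp_bins[::-1])
    dof = max(len(obs) - 2, 1)
    nz = obs > 0
    G = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return {"q_hat": float(q), "G": G, "chi2": chi2, "dof": dof,
            "p_G": float(stats.chi2.sf(G, dof)),
            "p_chi2": float(stats.chi2.sf(chi2, dof))}


def descendant_sequence(record: InsertRecord, rng: np.random.Generator,
                        f: np.ndarray, alphabet: str) -> str:
    """Realize a descendant sequence from one evolved record.

    Substitution dynamics are not simulated here (the substitution module
    owns residue evolution): surviving ancestral positions and inserted
    residues draw their identities from the background frequencies f.
    """
    cum = np.cumsum(f / f.sum())
    n = int(record.survived.sum() + record.insert_lengths.sum())
    draws = np.searchsorted(cum, rng.random(n))
    return "".join(alphabet[d] for d in draws)


def write_descendants_fasta(path, records: list[InsertRecord],
                            rng: np.random.Generator, f: np.ndarray,
                            alphabet: str, prefix: str = "descendant") -> None:
    with open(path, "w") as fh:
        for k, rec in enumerate(records):
            fh.write(f">{prefix}{k}\n")
            fh.write(descendant_sequence(rec, rng, f, alphabet) + "\n")


# ---------------------------------------------------------------------------
# macroscopic generative sampling


@dataclass
class PairSample:
    """A sampled homolog pair with its true alignment."""

    s1: str
    s2: str
    columns: list  # (i, j, homologous) as in AlignmentResult
    events1: str  # branch event strings over M/D/I
    events2: str
    ancestor_len: int

    def identity(self) -> float:
        """Percent identity: identical aligned pairs / min sequence length."""
        if min(len(self.s1), len(self.s2)) == 0:
            return 0.0
        ident = sum(1 for i, j, _ in self.columns
                    if i is not None and j is not None
                    and self.s1[i] == self.s2[j])
        return 100.0 * ident / min(len(self.s1), len(self.s2))

    def aligned_rows(self) -> tuple[str, str]:
        r1 = "".join(self.s1[i] if i is not None else "-"
                     for i, _, _ in self.columns)
        r2 = "".join(self.s2[j] if j is not None else "-"
                     for _, j, _ in self.columns)
        return r1, r2


def _sample_branch(ts, L: int, rng: np.random.Generator) -> str:
    """Event string of one branch descent over an ancestor of length L."""
    cum = np.cumsum(ts.t[:, 1:4], axis=1)
    cum /= cum[:, -1:]
    events = []
    state = 0  # B
    for _ in range(L):
        while True:
            y = int(np.searchsorted(cum[state], rng.random())) + 1
            events.append("MDI"[y - 1])
            state = y
            if y != 3:
                break
    while rng.random() < ts.t[state, 3]:
        events.append("I")
        state = 3
    return "".join(events)


def sample_pair(model_id: str, params, t1: float, t2: float,
                subst: SubstitutionModel, rng: np.random.Generator,
                ancestor_len: int | None = None,
                p_len: float | None = None,
                q_I: np.ndarray | None = None) -> PairSample:
    """Sample two extant homologs from a common ancestor, with truth.

    The ancestor length is fixed (``ancestor_len``) or geometric with
    parameter ``p_len`` (default: the model's implied p); residues are
    drawn from the substitution model's stationary frequencies, insert
    residues from ``q_I`` (default background).  Branch-1 inserts are
    placed before branch-2 inserts between ancestral positions, matching
    the alignment engine's canonical ordering.
    """
    if ancestor_len is None:
        p_len = ancestral_p(model_id, params) if p_len is None else p_len
        ancestor_len = int(rng.geometric(1.0 - p_len) - 1)
    ts1 = transitions_at(model_id, params, t1)
    ts2 = transitions_at(model_id, params, t2)
    ev1 = _sample_branch(ts1, ancestor_len, rng)
    ev2 = _sample_branch(ts2, ancestor_len, rng)
    f = subst.f
    qI = f if q_I is None else q_I
    P1 = subst.conditional_at(t1)
    P2 = subst.conditional_at(t2)
    K = len(f)
    anc = rng.choice(K, size=ancestor_len, p=f / f.sum())

    def _walk(events: str, P: np.ndarray):
        """Per ancestral position: (insert residues before it, fate residue)."""
        cumq = np.cumsum(qI / qI.sum())
        cumP = np.cumsum(P, axis=1)
        cumP /= cumP[:, -1:]
        out = []
        inserts: list[int] = []
        k = 0
        for e in events:
            if e == "I":
                inserts.append(int(np.searchsorted(cumq, rng.random())))
            elif e == "M":
                out.append((inserts,
                            int(np.searchsorted(cumP[anc[k]], rng.random()))))
                inserts = []
                k += 1
            else:  # D
                out.append((inserts, None))
                inserts = []
                k += 1
        return out, inserts  # trailing inserts

    walk1, trail1 = _walk(ev1, P1)
    walk2, trail2 = _walk(ev2, P2)
    s1: list[int] = []
    s2: list[int] = []
    columns: list = []
    for (ins1, fate1), (ins2, fate2) in zip(walk1, walk2):
        for c in ins1:
            columns.append((len(s1), None, True))
            s1.append(c)
        for c in ins2:
            columns.append((None, len(s2), True))
            s2.append(c)
        if fate1 is not None and fate2 is not None:
            columns.append((len(s1), len(s2), True))
            s1.append(fate1)
            s2.append(fate2)
        elif fate1 is not None:
            columns.append((len(s1), None, True))
            s1.append(fate1)
        elif fate2 is not None:
            columns.append((None, len(s2), True))
            s2.append(fate2)
        # double deletion: no observable column
    for c in trail1:
        columns.append((len(s1), None, True))
        s1.append(c)
    for c in trail2:
        columns.append((None, len(s2), True))
        s2.append(c)
    alph = subst.alphabet
    return PairSample(s1="".join(alph[c] for c in s1),
                      s2="".join(alph[c] for c in s2),
                      columns=columns, events1=ev1, events2=ev2,
                      ancestor_len=ancestor_len)
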