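"""Alignment accuracy and homology-coverage benchmarking.

Accuracy compares aligned residue pairs against a trusted reference:
SEN_A = correctly inferred aligned positions / true aligned positions,
PPV_A = correctly inferred / inferred, F = harmonic mean.  Reference
columns marked nonhomologous by the lowercase convention are excluded
from the truth set.

Coverage isolates the homologous-overextension artifact: it counts
residues included in aligned columns against the per-residue homology
truth, without penalizing homologous residues aligned to the wrong
homologous partner: SEN_C = homologous residues aligned / homologous
residues, PPV_C = homologous residues aligned / aligned residues.

Pairs are binned by reference percent identity (5 % bins, pooling
numerators and denominators within each bin) and summarized by the area
under the F-vs-identity curve (trapezoid over bin midpoints, normalized
by the identity span, in %).

The local-homology generator cuts one contiguous block (~N(50, 10)
columns) out of each reference alignment and replaces the flanking
residues with equal numbers of background residues randomized by
single-residue shuffling, requiring each flank to cover at least a fifth
of the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .substitution import AMINO_ACIDS, blosum62_model


def ungapped(row: str) -> str:
    return row.replace("-", "").replace(".", "")


def percent_identity(row1: str, row2: str) -> float:
    """100 * identical aligned positions / min(sequence lengths)."""
    if len(row1) != len(row2):
        raise ValueError("aligned rows must have equal length")
    n1, n2 = len(ungapped(row1)), len(ungapped(row2))
    if n1 == 0 or n2 == 0:
        raise ValueError("percent identity is undefined for empty sequences")
    ident = sum(1 for a, b in zip(row1, row2)
                if a not in "-." and b not in "-." and a.upper() == b.upper())
    return 100.0 * ident / min(n1, n2)


def aligned_pairs_from_rows(row1: str, row2: str,
                            skip_lowercase: bool = False) -> set:
    """Residue-index pairs occupying the same column of an alignment.

    With ``skip_lowercase``, columns where either residue is lowercase are
    excluded (the convention marking nonhomologous reference columns).
    """
    pairs = set()
    i = j = 0
    for a, b in zip(row1, row2):
        ra, rb = a not in "-.", b not in "-."
        if ra and rb:
            if not (skip_lowercase and (a.islower() or b.islower())):
                pairs.add((i, j))
        if ra:
            i += 1
        if rb:
            j += 1
    return pairs


def _as_pairs(alignment, skip_lowercase: bool = False) -> set:
    if isinstance(alignment, set):
        return alignment
    row1, row2 = alignment
    return aligned_pairs_from_rows(row1, row2, skip_lowercase)


def accuracy(predicted, reference) -> dict:
    """Alignment accuracy of a predicted vs a reference alignment.

    Inputs are (row1, row2) aligned strings or sets of index pairs.
    Returns SEN/PPV/F with the underlying counts (for pooled binning).
    A prediction with no aligned pairs reports PPV = 0 with a flag.
    """
    pred = _as_pairs(predicted)
    ref = _as_pairs(reference, skip_lowercase=True)
    correct = len(pred & ref)
    sen = correct / len(ref) if ref else 0.0
    ppv = correct / len(pred) if pred else 0.0
    return {
        "SEN": sen, "PPV": ppv, "F": f_measure(sen, ppv),
        "n_correct": correct, "n_ref": len(ref), "n_pred": len(pred),
        "degenerate": not pred,
    }


def coverage(predicted, hom1: np.ndarray, hom2: np.ndarray) -> dict:
    """Homology coverage of a predicted alignment.

    ``hom1``/``hom2`` are boolean per-residue homology truth flags.
    Misalignment among homologous residues is not penalized.
    """
    pred = _as_pairs(predicted)
    hom1 = np.asarray(hom1, dtype=bool)
    hom2 = np.asarray(hom2, dtype=bool)
    aligned1 = {i for i, _ in pred}
    aligned2 = {j for _, j in pred}
    n_hom = int(hom1.sum() + hom2.sum())
    n_aligned = len(aligned1) + len(aligned2)
    n_hom_aligned = sum(1 for i in aligned1 if hom1[i]) + \
        sum(1 for j in aligned2 if hom2[j])
    sen = n_hom_aligned / n_hom if n_hom else 0.0
    ppv = n_hom_aligned / n_aligned if n_aligned else 0.0
    return {
        "SEN": sen, "PPV": ppv, "F": f_measure(sen, ppv),
        "n_hom_aligned": n_hom_aligned, "n_hom": n_hom,
        "n_aligned": n_aligned,
    }


def f_measure(sen: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and positive predictive value."""
    if sen + ppv == 0.0:
        return 0.0
    return 2.0 * sen * ppv / (sen + ppv)


@dataclass
class BenchmarkRecord:
    """Per-pair accuracy and coverage with pooling counts."""

    pair_id: str
    identity: float
    acc: dict
    cov: dict | None = None

    @property
    def bin(self) -> int:
        return min(int(self.identity // 5) * 5, 95)


def bin_and_auc(records: list[BenchmarkRecord], which: str = "accuracy"
                ) -> tuple[dict, float]:
    """Pooled per-bin SEN/PPV/F and the AUC of F over identity bins.

    Within a bin, numerators and denominators are pooled over all pairs
    (a bin's F is the F of the pooled counts, not the mean of per-pair
    F).  The AUC is the trapezoidal mean of F over the occupied bin
    midpoints, returned in %.
    """
    if not records:
        raise ValueError("bin_and_auc requires at least one record")
    bins: dict[int, dict] = {}
    for rec in records:
        d = bins.setdefault(rec.bin, {"num": 0, "den_sen": 0, "den_ppv": 0,
                                      "n_pairs": 0})
        if which == "accuracy":
            d["num"] += rec.acc["n_correct"]
            d["den_sen"] += rec.acc["n_ref"]
            d["den_ppv"] += rec.acc["n_pred"]
        elif which == "coverage":
            if rec.cov is None:
                raise ValueError("record lacks coverage counts")
            d["num"] += rec.cov["n_hom_aligned"]
            d["den_sen"] += rec.cov["n_hom"]
            d["den_ppv"] += rec.cov["n_aligned"]
        else:
            raise ValueError(f"unknown measure {which!r}")
        d["n_pairs"] += 1
    summary = {}
    for b in sorted(bins):
        d = bins[b]
        sen = d["num"] / d["den_sen"] if d["den_sen"] else 0.0
        ppv = d["num"] / d["den_ppv"] if d["den_ppv"] else 0.0
        summary[b] = {"SEN": sen, "PPV": ppv, "F": f_measure(sen, ppv),
                      "n_pairs": d["n_pairs"]}
    mids = np.array([b + 2.5 for b in summary])
    fs = np.array([summary[b]["F"] for b in summary])
    if len(mids) == 1:
        auc = 100.0 * float(fs[0])
    else:
        auc = 100.0 * float(np.trapezoid(fs, mids) / (mids[-1] - mids[0]))
    return summary, auc


# ---------------------------------------------------------------------------
# local homology set construction


@dataclass
class LocalHomologyInstance:
    """A homologous fragment embedded in shuffled nonhomologous flanks."""

    row1: str  # reference alignment row, flanks lowercase
    row2: str
    seq1: str
    seq2: str
    frag1: tuple[int, int]  # 0-based half-open residue coordinates
    frag2: tuple[int, int]
    hom1: np.ndarray
    hom2: np.ndarray
    identity: float  # of the retained homologous block

    def reference_pairs(self) -> set:
        return aligned_pairs_from_rows(self.row1, self.row2,
                                       skip_lowercase=True)


def synthetic_background_pool(rng: np.random.Generator, size: int = 50_000,
                              f: np.ndarray | None = None,
                              alphabet: str = AMINO_ACIDS) -> str:
    """A synthetic residue pool drawn from background frequencies.

    Stands in for draws from a real sequence database when building
    nonhomologous flanks.
    """
    if f is None:
        f = blosum62_model().f
    return "".join(np.random.default_rng(rng.integers(2 ** 31)).choice(
        list(alphabet), size=size, p=f / f.sum()))


def _shuffled_draw(pool: str, n: int, rng: np.random.Generator) -> str:
    """A contiguous pool slice randomized by single-residue shuffling."""
    if n == 0:
        return ""
    start = int(rng.integers(0, len(pool) - n))
    chars = list(pool[start:start + n])
    rng.shuffle(chars)
    return "".join(chars)


def make_local_set(references: list[tuple[str, str]],
                   seed: int | np.random.Generator = 0,
                   fragment_mean: float = 50.0, fragment_sd: float = 10.0,
                   pool: str | None = None, max_tries: int = 100
                   ) -> list[LocalHomologyInstance]:
    """Embed one fragment of each reference alignment in shuffled flanks.

    Keeps a contiguous block of ~N(fragment_mean, fragment_sd) columns at
    a uniform-random position, replaces all other residues with
    equal-length shuffled background, and enforces that each flank covers
    at least a fifth of the alignment (resampling up to ``max_tries``;
    too-short alignments are skipped).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    if pool is None:
        pool = synthetic_background_pool(rng)
    out = []
    for idx, (row1, row2) in enumerate(references):
        C = len(row1)
        ok = False
        for _ in range(max_tries):
            width = int(round(rng.normal(fragment_mean, fragment_sd)))
            if width < 5 or width > C - 2:
                continue
            start = int(rng.integers(1, C - width + 1))
            # flank sizes in the emitted alignment (flank residues of the
            # two sequences are laid out in separate columns)
            left = len(ungapped(row1[:start])) + len(ungapped(row2[:start]))
            right = len(ungapped(row1[start + width:])) \
                + len(ungapped(row2[start + width:]))
            total = left + width + right
            if left >= total / 5.0 and right >= total / 5.0:
                ok = True
                break
        if not ok:
            continue
        block = slice(start, start + width)
        b1, b2 = row1[block].upper(), row2[block].upper()
        left1 = _shuffled_draw(pool, len(ungapped(row1[:start])), rng)
        right1 = _shuffled_draw(pool, len(ungapped(row1[block.stop:])), rng)
        left2 = _shuffled_draw(pool, len(ungapped(row2[:start])), rng)
        right2 = _shuffled_draw(pool, len(ungapped(row2[block.stop:])), rng)
        nb1, nb2 = ungapped(b1), ungapped(b2)
        seq1 = left1 + nb1 + right1
        seq2 = left2 + nb2 + right2
        hom1 = np.zeros(len(seq1), dtype=bool)
        hom1[len(left1):len(left1) + len(nb1)] = True
        hom2 = np.zeros(len(seq2), dtype=bool)
        hom2[len(left2):len(left2) + len(nb2)] = True
        # reference rows: lowercase unaligned flanks around the block
        r1 = left1.lower() + "-" * len(left2) + b1 \
            + right1.lower() + "-" * len(right2)
        r2 = "-" * len(left1) + left2.lower() + b2 \
            + "-" * len(right1) + right2.lower()
        ident = percent_identity(b1, b2) if nb1 and nb2 else 0.0
        out.append(LocalHomologyInstance(
            row1=r1, row2=r2, seq1=seq1, seq2=seq2,
            frag1=(len(left1), len(left1) + len(nb1)),
            frag2=(len(left2), len(left2) + len(nb2)),
            hom1=hom1, hom2=hom2, identity=ident))
    return out


# ---------------------------------------------------------------------------
# synthetic global set + end-to-end evaluation


def make_global_set(n_pairs: int, model_id: str, params, subst,
                    seed: int | np.random.Generator = 0,
                    t_range: tuple[float, float] = (0.05, 3.0),
                    ancestor_len: int = 100) -> list:
    """Sample reference homolog pairs across a spread of divergence times.

    Times are log-uniform over ``t_range`` so identity bins from near-0 to
    near-100 % are populated.  Returns (PairSample, t) tuples.
    """
    from .evolver import sample_pair

    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    out = []
    for _ in range(n_pairs):
        t = float(np.exp(rng.uniform(np.log(t_range[0]), np.log(t_range[1]))))
        ps = sample_pair(model_id, params, t / 2, t / 2, subst, rng,
                         ancestor_len=ancestor_len)
        if len(ps.s1) == 0 or len(ps.s2) == 0:
            continue
        out.append((ps, t))
    return out


def calibrate_branch_time(identity_target: float, model_id: str, params,
                          subst, seed: int = 0, n_pairs: int = 60,
                          ancestor_len: int = 150,
                          bounds: tuple[float, float] = (0.01, 6.0)) -> float:
    """Divergence time whose sampled alignments hit a mean percent identity.

    Bisects on t; identity decreases monotonically with t.  Used to define
    the short-branch (~71 % identity) and long-branch (~27 %) fixed
    parameterizations.
    """
    from .evolver import sample_pair

    def mean_identity(t: float) -> float:
        rng = np.random.default_rng(seed)
        ids = [sample_pair(model_id, params, t / 2, t / 2, subst, rng,
                           ancestor_len=ancestor_len).identity()
               for _ in range(n_pairs)]
        return float(np.mean(ids))

    lo, hi = bounds
    for _ in range(24):
        mid = np.sqrt(lo * hi)
        if mean_identity(mid) > identity_target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
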