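# Methods

## The problem

Affine-gap alignment (Smith–Waterman, BLAST, profile HMMs) scores an indel
of length n as open + n·extend, with one fixed score system regardless of
how diverged the two sequences actually are. This package implements a
family of continuous-time insertion/deletion models whose finite-time
behavior *is* an affine three-state pair HMM, so that substitution scores
and gap costs can be synchronized to a divergence time t and, when useful,
that time can be optimized per comparison.

## Microscopic and macroscopic models

A *microscopic* model specifies instantaneous event rates: how inserted
residues appear and disappear and how ancestral residues die. Solving its
differential equations gives the *macroscopic* model — finite-time
conditional probabilities that parameterize a pair HMM. An "insert" is the
collection of all residues inserted between two remembered ancestral
positions, whether or not the flanking ancestral residues are still alive.

The junction (insert) process implemented in `evolver` is the GM family:

* opening channel, rate λ, always active, adding a geometric(v_I) burst;
* expansion, rate λ_I per resident residue (burst geometric(v_I));
* an emptying channel at rate μ and per-residue shrinkage at rate μ_I for
  every residue beyond the first (bursts geometric(v_D), capped so only
  the emptying channel can clear the insert).

With λ = λ_I, μ = μ_I and no bursts — the aali special case — the
junction is exactly the immortal-link linear birth–death chain (birth
(n+1)λ, death nμ), whose occupancy is geometric with parameter

    β(t) = λ(1 − e^{(λ−μ)t}) / (μ − λ e^{(λ−μ)t})

at *every* t, the property affine gap costs require. Any departure —
unequal open/extend rates or bursts — breaks the geometric law at finite
times even when each elementary event is geometric, which the simulator
demonstrates by maximum-likelihood geometric fits with G and χ² tests
(tail bins pooled to expected counts ≥ 5, df = bins − 2). The per-event
semantics of the burst/removal channels is our reconstruction, chosen so
that the aali tie reduces exactly to the linear birth–death chain; the
event repertoire (rates λ, λ_I, μ, μ_I and burst parameters) is as in the
source model family.

Ancestral residues die at a context-dependent rate μ_A^X, where X is the
current state of the immediately preceding element: I if the adjacent
insert is nonempty, else D if the previous ancestral position is dead,
else M (μ_A^B = μ_A^M). The simulator is exact (event-driven per
junction; position death times sampled by integrating the
piecewise-constant hazard along each position's context path); a
discretized δt mode (default δt = 1e-5, implemented by geometric step
skipping, equivalent to the per-step Bernoulli scheme to first order in
δt) is provided and cross-checked against the exact engine by a
two-sample G-test.

Validation of the elementary functions against the simulator conditions
on constant-context exposure segments: given that a position's flanking
context stayed in state X over an interval of length d and the position
was alive at its start, the death probability is exactly
1 − e^{−μ_A^X d}; the tests compare observed death counts in those
segments to the summed expectations within 3 binomial standard errors.

## The model zoo

Elementary probability functions γ^X(t) (ancestral deletion), β^X(t)
(insert opening) and η(t) (insert extension) assemble into normalized
transitions

    t_XI = β^X,  t_XM = (1−β^X)(1−γ^X),  t_XD = (1−β^X)γ^X     (X = B,M,D)
    t_II = η + (1−η)β^I,  t_IM = (1−η)(1−β^I)(1−γ^I),  t_ID = (1−η)(1−β^I)γ^I

which sum to one for arbitrary elementary functions and reproduce the
published TKF91 transition matrix with TKF91's β and γ (verified against
numerical integration of the TKF91 birth–death process to 1e-6).

| model | free parameters | notes |
|-------|----------------|-------|
| tkf91 | λ, μ | no ancestral memory; β^D is the distinct "dead-link" function |
| tkf92 | λ, μ, r | fragments on all three states |
| li    | λ, μ, μ_A, p | linear, ancestral memory |
| lr    | λ, μ_A | μ = λ+μ_A, p = λ/μ_A; reversible |
| aali  | λ, μ, μ_A^{M,D,I}, p | affine ancestral deletions |
| afg   | aali + r_M, r_D, r_I | fragment derivative |
| afr   | λ, μ_A, r_M, r_X | reversible; Smith-Waterman compatible |
| aif   | aali + r_I | insert-only fragments (profile HMMs) |
| aga   | λ, μ, μ_A^{M,D,I}, s_I, p | time-independent geometric inserts |

For the aali family we use γ^X(t) = 1 − e^{−μ_A^X t} (state-specific
exponential survival) and the shared linear-insert β above; for lr these
satisfy the reversibility condition β = p(1−β)γ identically. The closed
forms for the aali/afg/aif/aga elementary functions are reconstructions
gated by simulator-agreement tests rather than asserted analytic results;
aga pins η = s_I (time-independent insert length) and reuses the
linear-insert opening curve, so its opening probability is validated
structurally (through the lr/aali machinery) while η is validated
directly.

Fragmentization wraps each self-looping state in indivisible geometric
fragments: row X is scaled by (1−r_X) and r_X is added to the self-loop.
In joint mode (ancestral-advance transitions carry the length factor p)
fragmentization is applied after the joint conversion, so p counts
fragments; the joint afr chain then has T_XX = β(1−r_X)+r_X and
T_MX = β(1−r_M), and is exactly invariant under exchanging the
insertion/deletion roles — the symmetry Smith-Waterman assumes. The TKF
models fail this swap test whenever λ ≠ μ.

## Divergence-synchronized gap costs

Reading the standard −11/−1 half-bit gap costs as the afr joint
transitions at an anchor time t* = 1 gives T*_XX = 2^{−1/2} ≈ 0.7071 and
T*_MX ≈ 0.0533, hence β* = T*_MX/(1−r_M); with β∞ = λ/(λ+μ_A) fixed, the
rates and the indel fragment parameter solve in closed form (see
`gapcost.solve_afr_from_anchor`). r_M = 0.75 and β∞ = 0.30 are the
package defaults; they are demonstration values chosen to track empirical
open/extend pairs used by FASTA/SSEARCH at other divergences, and are
exposed as configuration. The continuous-time costs are then

    extend(t) = 2 log2 [β(t)(1−r_X) + r_X]
    open(t)   = 2 log2 [β(t)(1−β(t))(1−r_X)(1−r_M) / (β(t)(1−r_X)+r_X)]

with the substitution score 2·log2 P_t(b|a)/f_b from the synchronized
matrix exp(tQ). Scores are kept real-valued in half bits; integer
rounding is a writer option.

## Substitution machinery

The default model anchors t = 1 to BLOSUM62. Because BLOSUM62 is
distributed as integer half-bit scores, the target probabilities are
recovered by solving for the matrix's implicit scale λ' such that
Σ_ab f_a f_b 2^{λ' S_ab} = 1 against a background amino-acid composition
(the standard inversion applied to integer matrices); the joint's
marginals, not the raw background, are the model frequencies f, which
makes f exactly stationary. Q is the principal matrix logarithm of the
conditional matrix (eigendecomposition, Schur fallback if
ill-conditioned); small negative off-diagonal artifacts (total ≈ 0.007
across the matrix) are clamped to zero with the diagonal rebalanced. The
clamp perturbs the rare-residue rows most (largest conditional deviation
≈ 0.05 on the cysteine diagonal); the fraction of substituted positions
at t = 1, 1 − Σ_a f_a P_1(a|a), is ≈ 69.9–70.0 %. The divergence scale
is the anchor scale throughout; substitutions-per-site is reported in the
score table, not used internally.

## The common-ancestor engine

A pair HMM relates an ancestor to one descendant, so two extant sequences
can be aligned directly only under a reversible model. For the
nonreversible members of the zoo the engine computes
P(s1, s2 | model, t1, t2) by summing over all ancestral sequences
(geometric length p, residues π) and all evolutionary histories, each
branch following its conditional transition functions at its branch time.
The dynamic program runs over the 16-state product of the two branch
chains; double deletions are non-emitting and are summed in closed form
by the geometric factor 1/(1 − p·t_DD·t_DD). Interleavings of branch-1
and branch-2 inserts between ancestral positions are canonicalized
(branch-1 inserts first), making the grammar unambiguous; the composite
construction is exactly branch-exchange symmetric when t1 = t2.
Everything runs in linear space with per-row rescaling (O(l1·l2) time and
memory), in a compiled kernel; scores are reported in nats.

Correctness is anchored by layered independent oracles: explicit
enumeration of branch event strings; a differently organized per-ancestor
conditional DP summed over every ancestral sequence up to a length bound
with a certified geometric tail; explicit enumeration of composite
histories (for Viterbi as the max); and, for local mode, composition of
global-oracle values over all flank/core segmentations. The production
kernel agrees with these to 1e-8 relative or better on exhaustive small
grids.

Local mode surrounds the homologous core(s) with nonhomologous flanks:
geometric(q) stretches of background residues, with an expected r/(1−r)
additional homologous regions. q = r = 0 reproduces the global model
exactly. Viterbi tracebacks carry per-column homology flags (core vs
flank).

The ancestral-length parameter p is decoupled from the lr/afr tie
p = λ/μ_A by default overrides where sequence length and indel rates
would otherwise be conflated: rate fitting fixes p from the data's mean
length, and the benchmark models use p = 0.99 (mean length ~100
fragments/residues). Branch-length optimization maximizes the forward
probability over one scalar t with t1 = t2 = t/2 (bounded search on
log t ∈ [log 1e-3, log 20], tolerance 1e-4, three-bracket multi-start,
ties toward smaller t). Score efficiency is the ratio of log-odds forward
scores (forward minus an independent-background null) at a fixed branch
to the optimum; it is meaningful when the optimal score is positive
(detectable homology). Rate fitting is quasi-Newton ascent with numerical
gradients on log-rates / logit-Bernoullis, deterministic given the
initial point.

Profile positions (per-position residue distributions instead of fixed
residues) are supported through the per-position emission arrays the
kernel consumes; progressive multiple alignment is out of scope.

## Benchmarks and what the synthetic data does (not) show

`benchmark` implements alignment accuracy (SEN/PPV/F over aligned residue
pairs, lowercase reference columns excluded) and homology coverage
(residues included in the alignment vs the per-residue homology truth,
misalignment among homologous residues not penalized). Pairs are binned
in 5 % identity bins (identity = identical aligned positions / min
sequence length); within a bin, numerators and denominators are pooled
before computing F. The AUC is the trapezoidal mean of F over occupied
bin midpoints, in % — the bin pooling follows the convention of summing
all alignments in a bin; the integration scheme itself is a fixed package
choice, comparable across runs of this package, not across publications.

The synthetic global set samples homolog pairs from the afr model
(ancestors of 175 residues; divergence log-uniform in [0.05, 1.8]), which
spans near-identical to barely-detectable pairs of realistic length. The
local set keeps one contiguous block of ~N(50, 10) columns per reference
alignment and replaces all other residues with equal-length
single-residue-shuffled draws from a synthetic background pool (a
stand-in for database draws), requiring each flank to cover at least a
fifth of the alignment. Fixed "short" and "long" parameterizations are
calibrated by bisection so sampled alignments average ~71 % and ~27 %
identity.

Two caveats that passing tests do *not* overturn: (1) the generator is
homogeneous-rate, so at matched identity its divergent pairs carry less
alignable signal than curated structural benchmarks, whose low-identity
pairs stay alignable through conserved cores — beyond t ≈ 1.8 at these
lengths the ML branch correctly saturates at "effectively unrelated";
(2) at 500 pairs, per-bin pooled F in the weak-signal bins (≲ 40 %
identity, ~15–45 pairs per bin) fluctuates by several hundredths, so
bin-level comparisons there are noisy even when set-level AUC ordering is
stable. On the local set we observe the expected ordering — optimal
branch best by accuracy AUC, short branch with the best conserved-bin
coverage PPV, long branch best in divergent bins — while the
per-bin "optimal within 0.02 of the best fixed branch" property fails in
a couple of weak-signal bins, where the full-sequence ML branch length
overshoots on marginal fragments (the likelihood is verified higher at
the overshooting branch; the corresponding alignment is worse).

Identifiability note: training indel rates from pairs at a single
divergence leaves a flat λ/μ_A ridge — an insertion in one branch and a
deletion in the other explain the same observable column, and at small t
both β and γ grow linearly so only λ+μ_A is well determined. Training
sets therefore span several divergences ({0.3, 1, 2, 3} in the recovery
experiment), where the different saturation levels of β(t) (→ β∞ < 0.5)
and γ(t) (→ 1) separate the two rates.

## Numerical choices

* Matrix exponentials via `scipy.linalg.expm`; matrix logarithm via
  eigendecomposition with a Schur fallback above condition 1e8.
* DP in linear space with per-row rescaling below 1e-60; contributions
  more than ~250 orders of magnitude below a row's maximum underflow to
  zero, which is far below every tolerance used.
* Viterbi resolves the non-emitting same-cell system (flank chain,
  double-deletion entry) by two relaxation passes; all cycles have weight
  < 1, so an optimal path never loops.
* Geometric-fit pooling threshold 5 expected counts; df = bins − 2.
* Tie-breaks: branch-length ties toward smaller t; bracket edges snapped
  when the optimum sits against them.
* Problem sizes in the test suite (ancestor length 175–300, 100–500
  pairs, 2×10^5 generative samples, simulation L = 2000) are scaled-down
  study conditions chosen to exercise every regime of the models at
  interactive runtimes.

## Known limitations

* Single-rate (no site-to-site rate variation) substitution and indel
  processes; no position-specific profile rates.
* The aali/afg/aif/aga elementary functions are validated reconstructions,
  not transcriptions of analytic derivations.
* The gap-cost generator emits score systems but does not patch an
  aligner, and no Karlin–Altschul significance calibration is done.
* Progressive multiple alignment, banded/linear-memory DP, and database
  search statistics are out of scope.
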