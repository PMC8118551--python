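# Methods

## The alignment model

An alignment between a template of length N₁ and a query of length N₂ is a
sequence of triples (i, j, u): u ∈ {M, Ix, Iy, Gh, Gt}, where M consumes one
residue of each protein, Ix only a template residue, Iy only a query residue,
and Gh/Gt consume exactly one residue of either protein in the head or tail
flank.  `-1` marks the unconsumed side.  Equivalently the alignment is a set
of binary variables z<sub>ij</sub><sup>u</sup> (capacity 5·N₁·N₂ in the grid
interior) subject to: every residue of both proteins is consumed exactly
once, consumed indices increase along the path, and at least one triple is a
match.

Because several triple orders describe the same aligned-pair set, one
canonical order is imposed: between two matches all Ix precede all Iy, and
within a flank all template-consuming gap triples precede all
query-consuming ones.  This makes the four representations (state string
within the 3-line text record, lattice path, triple list, binary variables)
mutually bijective.  A bare state string alone does not always determine the
flank split between the two proteins; `state_string_to_alignment` solves for
it and raises on the (rare) ambiguous case, while the 3-line text record is
always exact.

### Transition model

Feasible transitions (12 of 25): M→{M, Ix, Iy, Gt}, Ix→{M, Ix, Iy},
Iy→{M, Iy}, Gh→{M, Gh}, Gt→{Gt}.  Iy→Ix is forbidden (canonical ordering),
and Gh→Gt is forbidden, which forces at least one match.  The transition
scores of M→Gt, Gh→M, Gh→Gh and Gt→Gt are pinned to 0 so flanks are never
penalized and the alignment is local.  Transition scores default to 0
everywhere and are held fixed during training; the emission table carries
the learned signal.

Inside the dynamic programs Gh and Gt each split into template- and
query-consuming sub-states (7 internal states) with the canonical order
enforced as a sub-state transition ban; paths start in {M, Gh} and end in
{M, Gt}.  All recursions are in log space.  Emission indexing for
one-sided triples uses the most recently consumed residue on the silent
side (clamped at 0).

### Decoding and likelihood

* Viterbi maximizes emission + transition score; ties break deterministically
  by state preference M > Ix > Iy > Gh > Gt.
* Forward–backward yields log Z and the posterior usage of every emission
  cell; the match marginals P(z<sub>ij</sub><sup>M</sup>=1) feed MaxAcc.
* MaxAcc re-runs the same DP with the match posteriors as the only scores,
  maximizing the expected number of correctly aligned pairs (about twice the
  cost of one Viterbi pass, since it needs forward and backward sweeps).
* log-likelihood of a reference alignment = path score − log Z; its gradient
  in θ is observed-minus-expected emission counts, which is what training
  backpropagates.

All four quantities are tested to 1e-8 against exhaustive enumeration of all
valid alignments for N₁, N₂ ≤ 4 (and likelihoods sum to 1 exactly by
construction of the enumeration).

## Emission scorers

The linear scorer is θ<sub>ij</sub><sup>M</sup> = ⟨w, f(i,j)⟩ + b over nine
pairwise channels, with constant learned Ix/Iy penalties and zero Gh/Gt
scores.  The channels: residue identity; BLOSUM80/62/45 (from Biopython's
canonical tables; residue 'X' scores 0); profile products ⟨psfm_q, pssm_t⟩
and ⟨psfm_t, pssm_q⟩ (PSSMs are used unscaled); and agreement scores defined
as the probability the query's predicted class distribution assigns to the
template's observed class (3- and 8-class secondary structure, 3-class
solvent accessibility with buried/intermediate/exposed thresholds 0.10 and
0.40).  Templates without a profile fall back to a one-hot PSFM and a
log-odds PSSM of the background-blended PSFM (blend 0.1).

The deep scorer runs a 1D residual conv stack per protein (default 10
convolutions, kernel 3, instance norm + ReLU) over 54 per-position features,
lifts both 1D maps to the N₁×N₂ grid by outer concatenation, appends the
nine raw pairwise channels, and applies a 2D residual network (default 20
blocks of 3 convolutions, kernel 5×5) ending in a 1×1 head.  Channel widths
default to 32 (1D) and 64 (2D) and are configurable; desk-scale tests use
4–8.  By default the network emits only match scores and the insertion
penalties are learned scalars; an `emit_gap_scores` switch adds Ix/Iy output
channels.  Instance normalization can be disabled for exact comparison
against a plain re-evaluation of the layer sequence.

All layers are implemented in numpy with hand-written backward passes
(verified by directional finite differences to ~1e-9 relative); training
uses Adam (default lr 0.05 for the linear scorer) or plain gradient ascent,
with minibatches packed by length product n₁·n₂ (default budget 4096) so
each batch does comparable work.  Every stochastic routine takes an explicit
seed; identical inputs, parameters and seeds give bit-identical scores.

## Distance potential and threading objective

Distances are discretized into 14 bins.  The published bin listing skips the
4–5 Å interval; the only 14-interval reading with 1 Å steps is
{<4, [4,5), …, [15,16), ≥16} with right-open interior bins, which is what is
implemented.  The DFIRE reference distribution is p_ref(b) ∝ r_b^α with bin
midpoints r_b (the open last bin uses its lower edge + 0.5 Å), α = 1.61 (the
standard DFIRE exponent; configurable), and the potential
u = −log(p/p_ref) is clipped to ±10 to keep zero-probability bins finite.

The threading objective is maximized, so pair scores enter as −u (higher is
better).  S_pairwise sums over unordered distinct aligned pairs, excluding
self-pairs, and template pairs in the ≥16 Å bin contribute nothing; these
conventions (unordered, once each, hard 16 Å horizon) are fixed here because
any consistent choice works but mixing them silently rescales w.  w defaults
to 1; for easy targets, where the sequence signal is reliable, the `--easy`
flag raises it to 20.

## ADMM

The alignment variables are duplicated into copies z and y with consensus
z = y and objective w·θ·z + zᵀCy, where C carries half of each pair score so
the quadratic form equals S_pairwise at consensus.  Under the scaled
augmented Lagrangian each subproblem is linear in its binary variables
(z² = z), so both steps are Viterbi runs with the coupling and penalty terms
folded into the match emissions; duals update by the residual z − y.  The
first z-step runs without the penalty, so it is exactly "re-align against
the potential implied by the initial alignment" and reduces to plain Viterbi
when the potential vanishes.  Defaults: ρ = 0.5, max_iter = 20, residual
tolerance 1e-6.

ADMM on this non-convex problem can stall, so `keep_best` (default on)
returns the best true-objective alignment ever visited — never below the
initialization.  Leftover iteration budget after consensus is spent on
deterministic local search: best-response Viterbi steps against the full
coupling of the incumbent, plus a "kick" that forbids the incumbent's
weakest aligned pair when stalled.  On 4-residue synthetic instances at the
generator's default conditions this attains the exhaustively verified
optimum of the objective in 20/20 seeded instances per batch (the test
asserts ≥ 80%); on adversarial instances with i.i.d. random pair potentials
no such guarantee holds, and none is claimed.  Multi-start races ADMM from
the Viterbi alignments of several score tables (typically four differently
trained scorers) and keeps the best objective under the designated primary
table.

The network refiner builds three grid channels from an initial alignment —
its indicator matrix, θ<sup>M</sup>, and the summed pair score against the
initial alignment's pairs restricted to template partners within 16 Å
(self template position and self query position excluded) — and re-emits
match scores through a 2D residual network; refiner output is decoded by
Viterbi and can be interleaved with ADMM, carrying the best-so-far alignment
forward so the incumbent objective never decreases.

## Template ranking

SelectionScore = w₁·S_singleton + S_pairwise + w₂·S_norm with
S_norm = S_pairwise/n_aligned; w₁ = 1 (20 for easy targets), w₂ = 5.  The
normalized term prevents long low-quality alignments of large proteins from
outranking short accurate ones.  Ties break on higher S_singleton, then
template name.

## Synthetic data

`sample_fold` draws a self-avoiding persistent random walk with step length
3.7–3.9 Å (Cβ-like spacing), a clash floor of 3.5 Å between non-consecutive
residues, and a centroid pull that folds the chain back so that a
substantial fraction of residue pairs fall inside the 16 Å horizon — without
contacts the pairwise term would be vacuous.  `make_pair` derives the query
from the template by point mutations (rate per aligned residue) and
single-residue indels (rate/2 deletions, rate/2 insertions), records the
generative correspondence as the reference alignment, and fabricates the
query-side "predictions" from the hidden ground truth blended toward
uniform by a noise parameter: profile, 3/8-class secondary structure (from
the i→i+3 distance geometry), 3-class accessibility (from the 8 Å neighbor
count), and the distance distribution (one-hot at the true bin when
noise = 0; pairs involving inserted residues, which have no ground-truth
geometry, stay uniform).  Reference style "A" keeps all generative pairs;
style "B" trims the first and last pair, emulating reference builders that
discard uncertain flanks.  `make_dataset` cycles four difficulty levels
(mutation 0.10–0.60, indel 0.04–0.16) in the ratio 1:2:2:1 — emphasizing
medium difficulty — and splits train/validation/test by fold identity.

What the generator does not emulate: real backbone geometry and secondary-
structure statistics, profile statistics of deep MSAs, structurally
divergent homolog pairs whose reference alignment is itself uncertain, and
realistic distance-predictor error structure (noise here is uniform
smoothing).  Tests passing on these fixtures show the machinery is correct
and that the distance term rescues alignments when the sequence signal is
degraded; they do not certify accuracy on real proteins.

## Numerical and design notes

* All DPs in float64 log space; no probability-space recursions.
* Viterbi tie-breaks and the canonical triple order make every output
  deterministic; the CLI reproduces byte-identical artifacts given a seed
  (HDF5 files are written without modification times).
* Problem sizes in the test suite are chosen for exhaustive verifiability:
  enumeration oracles cover N₁, N₂ ≤ 4–5; training/ranking experiments use
  chains of 10–24 residues and corpora of up to 200 pairs.
* `loglik` of any valid alignment is finite for finite θ; overflow of the
  partition function raises rather than returning garbage.
* Known limitations: Gh/Gt cannot be trained (their scores are pinned by the
  locality convention); the ADMM subproblem linearization can cycle on
  adversarial potentials (mitigated but not eliminated by keep_best + local
  search); the deep scorer is CPU-bound numpy and intended for desk-scale
  experiments, not CASP-scale training.
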