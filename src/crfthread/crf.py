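"""Five-state pairwise-alignment conditional random field.

The CRF scores an alignment path as the sum of per-triple emission scores
``theta_ij^u`` and per-transition scores, over the states M, Ix, Iy, Gh, Gt.
This module provides the transition model, Viterbi decoding (highest-scoring
alignment), the forward-backward partition function with match posteriors,
maximum-expected-accuracy decoding, and the reference log-likelihood with its
gradient in ``theta`` (used for maximum-likelihood training).

Internally the head/tail gap states are each expanded into two directional
sub-states (template-consuming and query-consuming) so that the dynamic
program walks a lattice of ``(n1+1) x (n2+1)`` cells and 7 internal states;
results are collapsed back to the five public states.  All recursions run in
log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alignment import (
    DEFAULT_FEASIBLE,
    Alignment,
    AlignState,
    AlignmentError,
)

__all__ = [
    "ScoreTable",
    "TransitionModel",
    "PosteriorTable",
    "count_transitions",
    "viterbi",
    "forward_backward",
    "maxacc_decode",
    "loglik",
    "loglik_grad_theta",
    "score_alignment",
]

_NEG = -1.0e30

# internal states: M, Ix, Iy, GhX, GhY, GtX, GtY
_N_INT = 7
_COLLAPSE = np.array([0, 1, 2, 3, 3, 4, 4], dtype=np.int64)
_DI = np.array([1, 1, 0, 1, 0, 1, 0], dtype=np.int64)
_DJ = np.array([1, 0, 1, 0, 1, 0, 1], dtype=np.int64)
_START = np.array([1, 0, 0, 1, 1, 0, 0], dtype=np.bool_)  # M, GhX, GhY
_END = np.array([1, 0, 0, 0, 0, 1, 1], dtype=np.bool_)  # M, GtX, GtY


@dataclass
class ScoreTable:
    """Emission scores ``theta_ij^u`` on the ``(n1, n2, 5)`` grid.

    For insertion and flank-gap triples, which consume a residue on only one
    protein, the unconsumed index is taken to be the most recently consumed
    residue on that side (clamped to 0 at the start).  By default Gh/Gt
    emissions are identically zero so flanks are unpenalized (local
    alignment); a scorer may fill them in.
    """

    theta: np.ndarray
    n1: int = 0
    n2: int = 0

    def __post_init__(self):
        self.theta = np.ascontiguousarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 3 or self.theta.shape[2] != 5:
            raise ValueError("theta must have shape (n1, n2, 5)")
        self.n1, self.n2 = self.theta.shape[:2]
        if not np.isfinite(self.theta).all():
            raise ValueError("theta contains non-finite scores")


def _as_theta(theta) -> np.ndarray:
    th = theta.theta if isinstance(theta, ScoreTable) else np.asarray(theta)
    return np.ascontiguousarray(th, dtype=np.float64)


@dataclass
class TransitionModel:
    """Feasibility mask and transition scores over the 5x5 state pairs.

    The default model permits the 12 transitions
    M->{M,Ix,Iy,Gt}, Ix->{M,Ix,Iy}, Iy->{M,Iy}, Gh->{M,Gh}, Gt->{Gt}
    and forbids the other 13, including Iy->Ix (canonical gap ordering) and
    Gh->Gt (which would allow a match-free alignment).  The scores of
    M->Gt, Gh->M, Gh->Gh and Gt->Gt are fixed at 0 so head and tail gaps are
    never penalized.
    """

    feasible: np.ndarray = field(default_factory=lambda: DEFAULT_FEASIBLE.copy())
    score: np.ndarray = field(default_factory=lambda: np.zeros((5, 5)))

    def __post_init__(self):
        self.feasible = np.ascontiguousarray(self.feasible, dtype=bool)
        self.score = np.ascontiguousarray(self.score, dtype=np.float64)
        if self.feasible.shape != (5, 5) or self.score.shape != (5, 5):
            raise ValueError("transition model must be 5x5")
        # unpenalized-flank rule and infeasible entries carry score 0
        for u, v in _ZERO_SCORED:
            self.score[u, v] = 0.0
        self.score[~self.feasible] = 0.0

    def internal(self):
        """Expand to the 7 directional internal states."""
        feas = np.zeros((_N_INT, _N_INT), dtype=np.bool_)
        sc = np.zeros((_N_INT, _N_INT))
        for a in range(_N_INT):
            for b in range(_N_INT):
                ok = self.feasible[_COLLAPSE[a], _COLLAPSE[b]]
                # canonical: query-consuming flank gaps never precede
                # template-consuming ones within the same flank
                if (a, b) in ((4, 3), (6, 5)):
                    ok = False
                feas[a, b] = ok
                sc[a, b] = self.score[_COLLAPSE[a], _COLLAPSE[b]]
        return feas, sc


# transitions whose score is pinned to zero: M->Gt, Gh->M, Gh->Gh, Gt->Gt
_ZERO_SCORED = (
    (AlignState.M, AlignState.GT),
    (AlignState.GH, AlignState.M),
    (AlignState.GH, AlignState.GH),
    (AlignState.GT, AlignState.GT),
)


def count_transitions(tm: TransitionModel):
    """Count (feasible, forbidden) ordered state pairs; they sum to 25."""
    n_feasible = int(tm.feasible.sum())
    return n_feasible, 25 - n_feasible


@dataclass
class PosteriorTable:
    """Match posteriors ``P(z_ij^M = 1)`` and the log partition function.

    ``q5`` holds the full per-state posterior on the emission grid (the
    expected number of times each emission score is used), which is the
    gradient of ``logZ`` in ``theta``.
    """

    p_match: np.ndarray
    logZ: float
    q5: np.ndarray = None


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _emis(th, s, i, j):
    # (i, j) are consumed counts after the triple ending in internal state s
    if s == 0:
        return th[i - 1, j - 1, 0]
    if s == 1:
        return th[i - 1, max(j - 1, 0), 1]
    if s == 2:
        return th[max(i - 1, 0), j - 1, 2]
    if s == 3:
        return th[i - 1, max(j - 1, 0), 3]
    if s == 4:
        return th[max(i - 1, 0), j - 1, 3]
    if s == 5:
        return th[i - 1, max(j - 1, 0), 4]
    return th[max(i - 1, 0), j - 1, 4]


@njit(cache=True)
def _viterbi_kernel(th, feas, tsc):
    n1, n2 = th.shape[0], th.shape[1]
    f = np.full((n1 + 1, n2 + 1, _N_INT), _NEG)
    bp = np.full((n1 + 1, n2 + 1, _N_INT), -1, dtype=np.int8)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for s in range(_N_INT):
                pi, pj = i - _DI[s], j - _DJ[s]
                if pi < 0 or pj < 0:
                    continue
                best = _NEG
                arg = np.int8(-1)
                if pi == 0 and pj == 0:
                    if _START[s]:
                        best = 0.0
                        arg = np.int8(_N_INT)  # virtual start
                else:
                    for p in range(_N_INT):
                        if feas[p, s] and f[pi, pj, p] > _NEG / 2:
                            v = f[pi, pj, p] + tsc[p, s]
                            if v > best:
                                best = v
                                arg = np.int8(p)
                if arg >= 0:
                    f[i, j, s] = best + _emis(th, s, i, j)
                    bp[i, j, s] = arg
    return f, bp


@njit(cache=True)
def _forward_kernel(th, feas, tsc):
    n1, n2 = th.shape[0], th.shape[1]
    f = np.full((n1 + 1, n2 + 1, _N_INT), _NEG)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for s in range(_N_INT):
                pi, pj = i - _DI[s], j - _DJ[s]
                if pi < 0 or pj < 0:
                    continue
                acc = _NEG
                if pi == 0 and pj == 0:
                    if _START[s]:
                        acc = 0.0
                else:
                    for p in range(_N_INT):
                        if feas[p, s] and f[pi, pj, p] > _NEG / 2:
                            acc = np.logaddexp(acc, f[pi, pj, p] + tsc[p, s])
                if acc > _NEG / 2:
                    f[i, j, s] = acc + _emis(th, s, i, j)
    return f


@njit(cache=True)
def _backward_kernel(th, feas, tsc):
    n1, n2 = th.shape[0], th.shape[1]
    b = np.full((n1 + 1, n2 + 1, _N_INT), _NEG)
    for i in range(n1, -1, -1):
        for j in range(n2, -1, -1):
            for s in range(_N_INT):
                if _DI[s] > i or _DJ[s] > j:
                    continue  # state s cannot have produced this cell
                acc = _NEG
                if i == n1 and j == n2:
                    if _END[s]:
                        acc = 0.0
                else:
                    for t in range(_N_INT):
                        ni, nj = i + _DI[t], j + _DJ[t]
                        if ni > n1 or nj > n2 or not feas[s, t]:
                            continue
                        if b[ni, nj, t] > _NEG / 2:
                            acc = np.logaddexp(
                                acc, tsc[s, t] + _emis(th, t, ni, nj) + b[ni, nj, t]
                            )
                b[i, j, s] = acc
    return b


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _triples_from_backtrace(bp, end_state, n1, n2):
    states, cells = [], []
    i, j, s = n1, n2, end_state
    while True:
        states.append(s)
        cells.append((i, j))
        p = int(bp[i, j, s])
        if p == _N_INT:
            break
        i, j = i - int(_DI[s]), j - int(_DJ[s])
        s = p
    states.reverse()
    cells.reverse()
    triples = []
    for s, (ci, cj) in zip(states, cells):
        i = ci - 1 if _DI[s] else -1
        j = cj - 1 if _DJ[s] else -1
        triples.append((i, j, AlignState(int(_COLLAPSE[s]))))
    return triples


def viterbi(theta, tm: TransitionModel | None = None):
    """Highest-scoring valid alignment under emissions + transition scores.

    Returns ``(alignment, score)``.  Ties are broken deterministically by the
    state preference M > Ix > Iy > Gh > Gt.
    """
    tm = tm or TransitionModel()
    th = _as_theta(theta)
    feas, tsc = tm.internal()
    f, bp = _viterbi_kernel(th, feas, tsc)
    n1, n2 = th.shape[:2]
    best, arg = _NEG, -1
    for s in range(_N_INT):
        if _END[s] and f[n1, n2, s] > best:
            best, arg = f[n1, n2, s], s
    if arg < 0:
        raise AlignmentError("no feasible alignment (degenerate mask)")
    a = Alignment(_triples_from_backtrace(bp, arg, n1, n2), n1, n2).validate()
    return a, float(best)


def forward_backward(theta, tm: TransitionModel | None = None) -> PosteriorTable:
    """Log partition function and per-state posteriors, in log space."""
    tm = tm or TransitionModel()
    th = _as_theta(theta)
    n1, n2 = th.shape[:2]
    feas, tsc = tm.internal()
    f = _forward_kernel(th, feas, tsc)
    b = _backward_kernel(th, feas, tsc)
    ends = f[n1, n2, :][_END]
    logZ = float(np.logaddexp.reduce(ends))
    if not np.isfinite(logZ):
        raise FloatingPointError("partition function overflowed")
    q5 = np.zeros((n1, n2, 5))
    p_match = np.zeros((n1, n2))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for s in range(_N_INT):
                if f[i, j, s] <= _NEG / 2 or b[i, j, s] <= _NEG / 2:
                    continue
                q = np.exp(f[i, j, s] + b[i, j, s] - logZ)
                if s == 0:
                    q5[i - 1, j - 1, 0] += q
                    p_match[i - 1, j - 1] += q
                elif s == 1:
                    q5[i - 1, max(j - 1, 0), 1] += q
                elif s == 2:
                    q5[max(i - 1, 0), j - 1, 2] += q
                elif s in (3, 4):
                    ii = i - 1 if s == 3 else max(i - 1, 0)
                    jj = max(j - 1, 0) if s == 3 else j - 1
                    q5[ii, jj, 3] += q
                else:
                    ii = i - 1 if s == 5 else max(i - 1, 0)
                    jj = max(j - 1, 0) if s == 5 else j - 1
                    q5[ii, jj, 4] += q
    return PosteriorTable(p_match=np.clip(p_match, 0.0, 1.0), logZ=logZ, q5=q5)


def maxacc_decode(post: PosteriorTable, tm: TransitionModel | None = None) -> Alignment:
    """Alignment maximizing the expected number of correctly aligned pairs.

    Runs the same dynamic program as Viterbi with the match posteriors as the
    only emission scores and all transition scores zeroed (the feasibility
    mask is kept), so the decoded path maximizes the sum of ``p_match`` over
    its aligned pairs.
    """
    tm = tm or TransitionModel()
    n1, n2 = post.p_match.shape
    th = np.zeros((n1, n2, 5))
    th[:, :, 0] = post.p_match
    tm0 = TransitionModel(feasible=tm.feasible.copy(), score=np.zeros((5, 5)))
    a, _ = viterbi(th, tm0)
    return a


def _internal_path(a: Alignment):
    out = []
    for i, j, u in a.triples:
        if u == AlignState.M:
            out.append(0)
        elif u == AlignState.IX:
            out.append(1)
        elif u == AlignState.IY:
            out.append(2)
        elif u == AlignState.GH:
            out.append(3 if i >= 0 else 4)
        else:
            out.append(5 if i >= 0 else 6)
    return out


def score_alignment(a: Alignment, theta, tm: TransitionModel | None = None) -> float:
    """Total emission + transition score of one alignment path."""
    tm = tm or TransitionModel()
    a.validate()
    th = _as_theta(theta)
    _, tsc = tm.internal()
    path = _internal_path(a)
    total, ci, cj = 0.0, 0, 0
    for k, s in enumerate(path):
        ci += int(_DI[s])
        cj += int(_DJ[s])
        total += _emis.py_func(th, s, ci, cj)
        if k:
            total += tsc[path[k - 1], s]
    return float(total)


def loglik(a: Alignment, theta, tm: TransitionModel | None = None) -> float:
    """Log-probability of a reference alignment under the CRF (always <= 0)."""
    tm = tm or TransitionModel()
    return score_alignment(a, theta, tm) - forward_backward(theta, tm).logZ


def loglik_grad_theta(a: Alignment, theta, tm: TransitionModel | None = None):
    """Gradient of ``loglik`` with respect to the emission table.

    Equal to the observed emission-usage counts of the reference alignment
    minus their model expectation, returned as an ``(n1, n2, 5)`` array,
    together with the log-likelihood value: ``(ll, grad)``.
    """
    tm = tm or TransitionModel()
    th = _as_theta(theta)
    post = forward_backward(th, tm)
    obs = np.zeros_like(post.q5)
    path = _internal_path(a.validate())
    ci, cj = 0, 0
    for s in path:
        ci += int(_DI[s])
        cj += int(_DJ[s])
        if s == 0:
            obs[ci - 1, cj - 1, 0] += 1
        elif s == 1:
            obs[ci - 1, max(cj - 1, 0), 1] += 1
        elif s == 2:
            obs[max(ci - 1, 0), cj - 1, 2] += 1
        elif s in (3, 4):
            obs[ci - 1 if s == 3 else max(ci - 1, 0),
                max(cj - 1, 0) if s == 3 else cj - 1, 3] += 1
        else:
            obs[ci - 1 if s == 5 else max(ci - 1, 0),
                max(cj - 1, 0) if s == 5 else cj - 1, 4] += 1
    ll = score_alignment(a, th, tm) - post.logZ
    return ll, obs - post.q5
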