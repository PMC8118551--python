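"""ADMM alignment under the threading objective, multi-start, and ranking.

Maximizing ``S = w * S_singleton + S_pairwise`` over alignments is hard
because the pairwise distance term couples every pair of aligned positions.
We split the problem by duplicating the alignment variables into two copies
``z`` and ``y`` with a consensus constraint ``z = y`` and objective
``w * theta . z + z^T C y`` (``C`` carries half of each pair score, so the
quadratic form equals ``S_pairwise`` at consensus).  The scaled augmented
Lagrangian then decomposes into two singleton-only alignment problems: the
quadratic term, linearized against the other copy, and the quadratic penalty
(which is linear in binary variables) both fold into the match-state
emission scores, so each subproblem is solved exactly by Viterbi.  Dual
variables are updated by the scaled residual ``z - y``.  The first ``z``
update is run without the penalty term, so it is exactly "improve the
initial alignment against the distance potential held by ``y``"; with a
zero potential it reduces to plain Viterbi of the singleton scores.

ADMM on a non-convex combinatorial problem may stall in a local optimum, so
the best-objective alignment ever visited (including the initial one) is
returned, and several initial alignments (typically four, from differently
trained scorers) can be raced with :func:`multistart_align`.

Templates are ranked by the selection score

    SelectionScore = w1 * S_singleton + S_pairwise + w2 * S_norm

with ``S_norm = S_pairwise / n_aligned``; normalizing by alignment length
penalizes long, low-quality alignments.  Defaults: ``w1 = 1`` (raise to 20
for easy targets), ``w2 = 5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, aligned_pairs
from .crf import TransitionModel, viterbi, forward_backward, maxacc_decode
from .distance import DistancePotential, ObjectiveValue, objective
from .crf import _as_theta

__all__ = [
    "AdmmConfig",
    "AdmmResult",
    "SelectionResult",
    "admm_align",
    "multistart_align",
    "selection_score",
    "rank_templates",
]


@dataclass(frozen=True)
class AdmmConfig:
    """ADMM hyper-parameters: penalty weight, iteration cap, residual
    tolerance, and whether to return the best alignment ever visited."""

    rho: float = 0.5
    max_iter: int = 20
    tol: float = 1e-6
    keep_best: bool = True

    def __post_init__(self):
        if self.rho <= 0 or self.max_iter < 1:
            raise ValueError("rho must be > 0 and max_iter >= 1")


@dataclass
class AdmmResult:
    alignment: Alignment
    objective: ObjectiveValue
    trace: list
    converged: bool
    n_iter: int


def _coupling(pairs, u: np.ndarray, tbins: np.ndarray, n1: int, n2: int):
    """(C y) as a match-score grid: half the pair score against each aligned
    pair of the other copy, zero beyond the 16-Angstrom bin."""
    out = np.zeros((n1, n2))
    last = u.shape[2] - 1
    for (k, l) in pairs:
        b = tbins[:, k]
        contrib = -0.5 * u[:, l, :][:, b].T  # [i, j] = -u[j, l, b(i,k)] / 2
        contrib[b == last, :] = 0.0
        contrib[k, :] = 0.0
        contrib[:, l] = 0.0
        out += contrib
    return out


def _indicator(pairs, n1, n2):
    z = np.zeros((n1, n2))
    for (i, j) in pairs:
        z[i, j] = 1.0
    return z


def admm_align(
    theta,
    u,
    tbins,
    init: Alignment,
    w: float = 1.0,
    cfg: AdmmConfig | None = None,
    tm: TransitionModel | None = None,
) -> AdmmResult:
    """Improve an initial alignment under the threading objective by ADMM.

    The returned objective is never below the initial alignment's
    (``keep_best`` contract); ``converged=False`` flags hitting the
    iteration cap with a non-zero consensus residual.
    """
    cfg = cfg or AdmmConfig()
    tm = tm or TransitionModel()
    th = _as_theta(theta)
    up = u.u if isinstance(u, DistancePotential) else np.asarray(u, float)
    tb = np.asarray(tbins)
    n1, n2 = th.shape[:2]

    def true_obj(a):
        return objective(a, th, up, tb, w)

    best_a, best_o = init.validate(), true_obj(init)
    trace = [best_o.s_total]

    y_pairs = aligned_pairs(init)
    du = np.zeros((n1, n2))
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        pen = 0.0 if it == 1 else cfg.rho
        # z-step: singleton scores plus linearized coupling and penalty
        th_z = np.zeros_like(th)
        th_z[:, :, :3] = w * th[:, :, :3]
        th_z[:, :, 0] += _coupling(y_pairs, up, tb, n1, n2)
        th_z[:, :, 0] += pen * (_indicator(y_pairs, n1, n2) - du) - pen / 2.0
        z_align, _ = viterbi(th_z, tm)
        z_pairs = aligned_pairs(z_align)
        oz = true_obj(z_align)
        if not cfg.keep_best or oz.s_total > best_o.s_total:
            best_a, best_o = z_align, oz
        # y-step
        th_y = np.zeros_like(th)
        th_y[:, :, 0] = _coupling(z_pairs, up, tb, n1, n2)
        th_y[:, :, 0] += cfg.rho * (_indicator(z_pairs, n1, n2) + du) - cfg.rho / 2.0
        y_align, _ = viterbi(th_y, tm)
        y_pairs = aligned_pairs(y_align)
        oy = true_obj(y_align)
        if cfg.keep_best and oy.s_total > best_o.s_total:
            best_a, best_o = y_align, oy
        trace.append(max(oz.s_total, oy.s_total))
        resid = _indicator(z_pairs, n1, n2) - _indicator(y_pairs, n1, n2)
        if np.abs(resid).sum() <= cfg.tol:
            converged = True
            break
        du += resid

    # spend any leftover iteration budget on deterministic local search:
    # best-response steps (Viterbi against the full coupling of the best
    # alignment so far) and, when those stall, a "kick" that forbids the
    # weakest aligned pair to escape the local optimum.  keep_best makes
    # this phase monotone in the true objective.
    n_admm_iter = it
    kicked = set()
    used = it
    while cfg.keep_best and used < cfg.max_iter:
        used += 1
        bp = aligned_pairs(best_a)
        th_b = np.zeros_like(th)
        th_b[:, :, :3] = w * th[:, :, :3]
        th_b[:, :, 0] += 2.0 * _coupling(bp, up, tb, n1, n2)
        cand, _ = viterbi(th_b, tm)
        oc = true_obj(cand)
        if oc.s_total > best_o.s_total + 1e-12:
            best_a, best_o = cand, oc
            trace.append(oc.s_total)
            continue
        weakest, weakest_val = None, np.inf
        for (i, j) in sorted(bp):
            if (i, j) in kicked:
                continue
            val = w * th[i, j, 0]
            for (k, l) in bp:
                b = tb[i, k]
                if (k, l) != (i, j) and b < up.shape[2] - 1:
                    val += -up[j, l, b]
            if val < weakest_val:
                weakest, weakest_val = (i, j), val
        if weakest is None:
            break
        kicked.add(weakest)
        th_b[weakest[0], weakest[1], 0] = -1e6
        cand, _ = viterbi(th_b, tm)
        oc = true_obj(cand)
        trace.append(oc.s_total)
        if oc.s_total > best_o.s_total + 1e-12:
            best_a, best_o = cand, oc
    return AdmmResult(best_a, best_o, trace, converged, n_admm_iter)


def multistart_align(
    theta_list,
    u,
    tbins,
    w: float = 1.0,
    cfg: AdmmConfig | None = None,
    tm: TransitionModel | None = None,
    primary=None,
):
    """Race ADMM from the Viterbi alignment of each score table.

    ``primary`` designates the table whose singleton scores define the
    objective (default: the first); the other tables only contribute
    initial alignments.  Returns the best :class:`AdmmResult`.
    """
    if not theta_list:
        raise ValueError("at least one score table is required")
    tm = tm or TransitionModel()
    primary = primary if primary is not None else theta_list[0]
    best = None
    for th in theta_list:
        init, _ = viterbi(th, tm)
        res = admm_align(primary, u, tbins, init, w=w, cfg=cfg, tm=tm)
        if best is None or res.objective.s_total > best.objective.s_total:
            best = res
    return best


@dataclass(frozen=True)
class SelectionResult:
    """Template-ranking score and its components."""

    score: float
    s_singleton: float
    s_pairwise: float
    s_norm: float
    n_aligned: int
    w1: float = 1.0
    w2: float = 5.0


def selection_score(
    a: Alignment, theta, u=None, tbins=None, w1: float = 1.0, w2: float = 5.0
) -> SelectionResult:
    """SelectionScore = w1 * S_singleton + S_pairwise + w2 * S_norm.

    Without a distance potential (``u`` is None) the pairwise terms are zero
    and the score reduces to the weighted singleton alignment score.
    """
    obj = objective(
        a,
        theta,
        u if u is not None else np.zeros((a.n2, a.n2, 1)),
        tbins if tbins is not None else np.zeros((a.n1, a.n1), dtype=int),
        w=1.0,
    )
    n_aligned = len(aligned_pairs(a))
    s_norm = obj.s_pairwise / n_aligned
    return SelectionResult(
        score=w1 * obj.s_singleton + obj.s_pairwise + w2 * s_norm,
        s_singleton=obj.s_singleton,
        s_pairwise=obj.s_pairwise,
        s_norm=s_norm,
        n_aligned=n_aligned,
        w1=w1,
        w2=w2,
    )


def rank_templates(
    query,
    templates,
    scorer,
    pot: DistancePotential | None = None,
    mode: str = "drnf",
    decoder: str = "viterbi",
    w: float = 1.0,
    w1: float = 1.0,
    w2: float = 5.0,
    cfg: AdmmConfig | None = None,
    tm: TransitionModel | None = None,
    top_k: int | None = None,
):
    """Align the query to each template and rank by selection score.

    ``mode="drnf"`` decodes the emission scores directly (Viterbi or MaxAcc);
    ``mode="distance"`` additionally runs ADMM with the query's distance
    potential.  Ties break on higher singleton score, then template name.
    Returns ``[(template_name, SelectionResult, Alignment), ...]`` sorted
    best-first, truncated to ``top_k`` if given.
    """
    from .distance import template_distance_bins

    if not templates:
        raise ValueError("at least one template is required")
    if mode == "distance" and pot is None:
        raise ValueError("distance mode requires the query distance potential")
    tm = tm or TransitionModel()
    rows = []
    for t in templates:
        theta = scorer.score(query, t)
        if decoder == "maxacc":
            a = maxacc_decode(forward_backward(theta, tm), tm)
        else:
            a, _ = viterbi(theta, tm)
        tb = template_distance_bins(t.dist)
        if mode == "distance":
            a = admm_align(theta, pot, tb, a, w=w, cfg=cfg, tm=tm).alignment
            sel = selection_score(a, theta, pot, tb, w1=w1, w2=w2)
        else:
            sel = selection_score(a, theta, w1=w1, w2=w2)
        rows.append((t.name, sel, a))
    rows.sort(key=lambda r: (-r[1].score, -r[1].s_singleton, r[0]))
    return rows[:top_k] if top_k else rows
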