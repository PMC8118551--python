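"""Distance discretization, DFIRE potential and the threading objective.

Inter-residue Cbeta-Cbeta distances are discretized into 14 bins:
``[0, 4)``, thirteen 1 Angstrom steps ``[4, 5) ... [15, 16)``, and
``[16, inf)``.  A predicted query distance distribution over these bins is
converted to a statistical potential against the DFIRE reference state
(reference probability of bin *b* proportional to ``r_b ** alpha`` with the
bin midpoint ``r_b`` and exponent ``alpha = 1.61``):

    u(j, l, b) = -log( p(j, l, b) / p_ref(b) ),   clipped to +-clip.

A candidate alignment is scored by the threading objective

    S = w * S_singleton + S_pairwise

where ``S_singleton`` sums the emission scores ``theta_ij^u`` over the
alignment's triples and ``S_pairwise`` sums, over unordered pairs of aligned
positions ``(i, j)`` and ``(k, l)``, the score ``-u(j, l, b(i, k))`` of
placing query residues *j, l* at the template distance bin of residues
*i, k*.  Template pairs beyond 16 Angstrom (the last bin) contribute nothing,
which keeps the pairwise term local.  Higher is better throughout; the weight
``w`` defaults to 1 and may be raised (e.g. to 20) for easy targets where the
sequence signal is trustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, AlignState
from .crf import _as_theta

__all__ = [
    "DistanceBins",
    "DistanceDistribution",
    "DistancePotential",
    "dfire_potential",
    "template_distance_bins",
    "pairwise_score",
    "singleton_score",
    "objective",
    "ObjectiveValue",
    "N_BINS",
]

N_BINS = 14


@dataclass(frozen=True)
class DistanceBins:
    """The 14-interval distance discretization on ``[0, inf)``.

    Boundaries are the 13 thresholds 4, 5, ..., 16 Angstrom; interior bins
    are right-open, so bin 0 is ``[0, 4)`` and bin 13 is ``[16, inf)``.
    """

    boundaries: np.ndarray = field(
        default_factory=lambda: np.arange(4.0, 17.0)
    )

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + 1

    def discretize(self, d):
        """Map distance(s) in Angstrom to bin indices."""
        arr = np.asarray(d, dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("distances must be finite and non-negative")
        out = np.searchsorted(self.boundaries, arr, side="right")
        return out if arr.ndim else int(out)

    def midpoints(self) -> np.ndarray:
        """Representative radius per bin; the open last bin uses its lower
        edge + 0.5 Angstrom."""
        b = self.boundaries
        mids = np.empty(self.n_bins)
        mids[0] = b[0] / 2.0
        mids[1:-1] = (b[:-1] + b[1:]) / 2.0
        mids[-1] = b[-1] + 0.5
        return mids


@dataclass
class DistanceDistribution:
    """Predicted query Cbeta-Cbeta distance distribution ``p(j, l, bin)``.

    Symmetric in ``(j, l)``; rows sum to 1; the diagonal is unused.
    """

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        n = self.p.shape[0]
        if self.p.ndim != 3 or self.p.shape[1] != n:
            raise ValueError("p must have shape (n2, n2, n_bins)")
        off = ~np.eye(n, dtype=bool)
        sums = self.p.sum(axis=2)[off]
        if n > 1 and (np.abs(sums - 1.0) > 1e-6).any():
            raise ValueError("distance distribution rows must sum to 1")
        if not np.allclose(self.p, self.p.transpose(1, 0, 2), atol=1e-8):
            raise ValueError("distance distribution must be (j,l)-symmetric")


@dataclass
class DistancePotential:
    """DFIRE-referenced potential ``u(j, l, bin)``; lower u = more favorable."""

    u: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float64)
        if not np.isfinite(self.u).all():
            raise ValueError("potential must be finite (apply clipping)")


def dfire_reference(bins: DistanceBins | None = None, alpha: float = 1.61):
    """DFIRE reference distribution ``p_ref(b) ~ r_b ** alpha`` over bins."""
    bins = bins or DistanceBins()
    r = bins.midpoints() ** alpha
    return r / r.sum()


def dfire_potential(
    dist: DistanceDistribution,
    alpha: float = 1.61,
    clip: float = 10.0,
    bins: DistanceBins | None = None,
) -> DistancePotential:
    """Convert a distance distribution to a clipped DFIRE potential."""
    p_ref = dfire_reference(bins, alpha)
    with np.errstate(divide="ignore"):
        u = -np.log(dist.p / p_ref[None, None, :])
    return DistancePotential(np.clip(u, -clip, clip))


def template_distance_bins(dist_matrix, bins: DistanceBins | None = None):
    """Bin a template's symmetric Cbeta distance matrix."""
    bins = bins or DistanceBins()
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-6):
        raise ValueError("distance matrix must be square and symmetric")
    return bins.discretize(d)


def pairwise_score(a: Alignment, u: DistancePotential, tbins) -> float:
    """``S_pairwise``: sum of ``-u(j, l, tbins(i, k))`` over unordered
    distinct aligned pairs; template pairs in the last (>16 A) bin score 0."""
    a.validate()
    up = u.u if isinstance(u, DistancePotential) else np.asarray(u, float)
    tb = np.asarray(tbins)
    pairs = [(i, j) for i, j, st in a.triples if st == AlignState.M]
    if len(pairs) < 2:
        return 0.0
    ti = np.array([p[0] for p in pairs])
    qj = np.array([p[1] for p in pairs])
    b = tb[ti[:, None], ti[None, :]]
    s = -up[qj[:, None], qj[None, :], b]
    s[b == up.shape[2] - 1] = 0.0
    np.fill_diagonal(s, 0.0)
    return float(np.triu(s, 1).sum())


def singleton_score(a: Alignment, theta) -> float:
    """``S_singleton``: sum of emission scores over the alignment's triples
    (no transition scores; the emission-index convention of the CRF)."""
    th = _as_theta(theta)
    a.validate()
    total, ci, cj = 0.0, 0, 0
    for i, j, st in a.triples:
        ci += i >= 0
        cj += j >= 0
        total += th[max(ci - 1, 0), max(cj - 1, 0), st]
    return float(total)


@dataclass(frozen=True)
class ObjectiveValue:
    """Decomposed value of the threading objective."""

    s_total: float
    s_singleton: float
    s_pairwise: float
    w: float = 1.0


def objective(a: Alignment, theta, u: DistancePotential, tbins, w: float = 1.0):
    """Evaluate ``S = w * S_singleton + S_pairwise`` for one alignment."""
    s1 = singleton_score(a, theta)
    s2 = pairwise_score(a, u, tbins)
    return ObjectiveValue(w * s1 + s2, s1, s2, w)
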