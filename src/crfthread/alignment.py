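"""Pairwise query-template alignment data model.

An alignment between a template (length ``n1``, index ``i``) and a query
(length ``n2``, index ``j``) is an ordered sequence of triples ``(i, j, u)``
where ``u`` is one of five states:

* ``M``  -- residue *i* of the template is aligned to residue *j* of the query
  (consumes one residue of each protein),
* ``Ix`` -- insertion in the template (consumes one template residue; the
  query side is ``-1``),
* ``Iy`` -- insertion in the query (consumes one query residue; the template
  side is ``-1``),
* ``Gh`` -- head (leading) gap: one residue of either protein skipped before
  the first aligned pair,
* ``Gt`` -- tail (trailing) gap: one residue of either protein skipped after
  the last aligned pair.

``-1`` always marks the unconsumed side of a triple.  Every residue of both
proteins appears in exactly one triple, and every valid alignment contains at
least one ``M`` triple.

Canonical ordering
------------------
Several triple orderings can describe the same set of aligned pairs.  We use
one canonical form: within a region between two matches all ``Ix`` triples
precede all ``Iy`` triples, and within the head (resp. tail) region all
template-consuming ``Gh`` (``Gt``) triples precede all query-consuming ones.
The strict validator rejects non-canonical orderings; ``canonicalize`` rewrites
them.

The same alignment can be expressed as a state string, a path in the
``(n1+1) x (n2+1)`` alignment lattice, the triple list, or a set of binary
indicator variables ``z_ij^u`` of capacity ``5*(n1+1)*(n2+1)``; conversions
between all four are provided and round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AlignState",
    "Alignment",
    "AlignmentMatrix",
    "AlignEvalResult",
    "AlignmentError",
    "triples_to_matrix",
    "matrix_to_triples",
    "aligned_pairs",
    "evaluate_alignment",
    "write_alignment_text",
    "read_alignment_text",
    "write_alignment_a3m",
]


class AlignmentError(ValueError):
    """Raised when an alignment violates a structural invariant."""


class AlignState(IntEnum):
    """The five alignment states."""

    M = 0
    IX = 1
    IY = 2
    GH = 3
    GT = 4


#: one-letter code used in state strings and the text format
STATE_CHARS = "MXYHT"
_CHAR_TO_STATE = {c: AlignState(k) for k, c in enumerate(STATE_CHARS)}

# default 5x5 feasibility mask (rows: from-state, cols: to-state).
# M->{M,Ix,Iy,Gt}, Ix->{M,Ix,Iy}, Iy->{M,Iy}, Gh->{M,Gh}, Gt->{Gt};
# Iy->Ix and Gh->Gt (and everything into Gh except Gh itself) are forbidden.
DEFAULT_FEASIBLE = np.array(
    [
        [1, 1, 1, 0, 1],
        [1, 1, 1, 0, 0],
        [1, 0, 1, 0, 0],
        [1, 0, 0, 1, 0],
        [0, 0, 0, 0, 1],
    ],
    dtype=bool,
)
#: states a path may start in / end in
START_STATES = (AlignState.M, AlignState.GH)
END_STATES = (AlignState.M, AlignState.GT)


@dataclass(frozen=True)
class Alignment:
    """An alignment as an ordered list of ``(i, j, state)`` triples."""

    triples: tuple
    n1: int
    n2: int

    def __init__(self, triples: Iterable, n1: int, n2: int):
        object.__setattr__(
            self,
            "triples",
            tuple((int(i), int(j), AlignState(u)) for i, j, u in triples),
        )
        object.__setattr__(self, "n1", int(n1))
        object.__setattr__(self, "n2", int(n2))

    def __len__(self) -> int:
        return len(self.triples)

    # -- representation conversions ------------------------------------

    def state_string(self) -> str:
        """One character per triple, over the alphabet ``MXYHT``."""
        return "".join(STATE_CHARS[u] for _, _, u in self.triples)

    def path(self) -> list:
        """Lattice path: cumulative (template, query) residues consumed
        after each triple, starting from the implicit origin ``(0, 0)``."""
        out, ti, qj = [], 0, 0
        for i, j, _u in self.triples:
            ti += i >= 0
            qj += j >= 0
            out.append((ti, qj))
        return out

    def validate(self, strict: bool = True) -> "Alignment":
        """Check all structural invariants; return ``self``.

        With ``strict=False`` the canonical-ordering rules (Ix before Iy,
        template-consuming flank gaps before query-consuming ones) are not
        enforced, only structural consistency.
        """
        _validate(self, strict=strict)
        return self

    def canonicalize(self) -> "Alignment":
        """Return the canonical reordering of this alignment."""
        a = _validate(self, strict=False)
        return a

    def __repr__(self) -> str:  # compact, for test failure messages
        return f"Alignment({self.state_string()!r}, n1={self.n1}, n2={self.n2})"


def _segments(a: Alignment):
    """Split triples into head, interior, tail segments."""
    ts = a.triples
    k0 = 0
    while k0 < len(ts) and ts[k0][2] == AlignState.GH:
        k0 += 1
    k1 = len(ts)
    while k1 > k0 and ts[k1 - 1][2] == AlignState.GT:
        k1 -= 1
    return ts[:k0], ts[k0:k1], ts[k1:]


def _validate(a: Alignment, strict: bool) -> Alignment:
    if a.n1 < 1 or a.n2 < 1:
        raise AlignmentError("protein lengths must be >= 1")
    t_seen, q_seen = [], []
    for k, (i, j, u) in enumerate(a.triples):
        if u == AlignState.M:
            if i < 0 or j < 0:
                raise AlignmentError(f"triple {k}: M must consume both sides")
        elif u == AlignState.IX:
            if i < 0 or j != -1:
                raise AlignmentError(f"triple {k}: Ix must be (i, -1)")
        elif u == AlignState.IY:
            if i != -1 or j < 0:
                raise AlignmentError(f"triple {k}: Iy must be (-1, j)")
        else:  # GH / GT consume exactly one residue of either protein
            if (i >= 0) == (j >= 0):
                raise AlignmentError(
                    f"triple {k}: {u.name} must consume exactly one side"
                )
        if i >= a.n1 or j >= a.n2 or i < -1 or j < -1:
            raise AlignmentError(f"triple {k}: index out of range")
        if i >= 0:
            t_seen.append(i)
        if j >= 0:
            q_seen.append(j)
    if t_seen != list(range(a.n1)):
        raise AlignmentError(
            "template positions must each be consumed exactly once, in order"
        )
    if q_seen != list(range(a.n2)):
        raise AlignmentError(
            "query positions must each be consumed exactly once, in order"
        )
    states = [u for _, _, u in a.triples]
    if AlignState.M not in states:
        raise AlignmentError("alignment must contain at least one M triple")

    head, interior, tail = _segments(a)
    for seg, name, st in ((head, "head", AlignState.GH), (tail, "tail", AlignState.GT)):
        if any(u != st for _, _, u in seg):
            raise AlignmentError(f"{name} gap segment mixes states")
    if any(u in (AlignState.GH, AlignState.GT) for _, _, u in interior):
        raise AlignmentError("Gh/Gt may only appear as contiguous flanks")
    if interior and (
        interior[0][2] != AlignState.M or interior[-1][2] != AlignState.M
    ):
        raise AlignmentError("interior must start and end with M")

    # transition feasibility at the collapsed 5-state level
    for k in range(1, len(a.triples)):
        u, v = a.triples[k - 1][2], a.triples[k][2]
        if not DEFAULT_FEASIBLE[u, v]:
            if strict or (u, v) not in (
                (AlignState.IY, AlignState.IX),
            ):
                raise AlignmentError(f"infeasible transition {u.name}->{v.name}")

    if strict:
        # canonical ordering inside head/tail and Ix/Iy runs
        for seg, name in ((head, "head"), (tail, "tail")):
            seen_q = False
            for i, j, _u in seg:
                if j >= 0:
                    seen_q = True
                elif seen_q:
                    raise AlignmentError(
                        f"non-canonical {name} gap: template-consuming triple "
                        "after query-consuming triple"
                    )
        return a

    # non-strict: rebuild canonically from the consumption pattern
    def _reorder(seg, st):
        xs = sorted([t for t in seg if t[0] >= 0])
        ys = sorted([t for t in seg if t[1] >= 0], key=lambda t: t[1])
        return [(i, j, st) for i, j, _ in xs + ys]

    fixed = _reorder(head, AlignState.GH)
    run_x, run_y = [], []
    for tr in interior:
        if tr[2] == AlignState.IX:
            run_x.append(tr)
        elif tr[2] == AlignState.IY:
            run_y.append(tr)
        else:
            fixed.extend(run_x + run_y)
            run_x, run_y = [], []
            fixed.append(tr)
    fixed.extend(run_x + run_y)
    fixed.extend(_reorder(tail, AlignState.GT))
    out = Alignment(fixed, a.n1, a.n2)
    return _validate(out, strict=True)


# ---------------------------------------------------------------------------
# binary indicator representation
# ---------------------------------------------------------------------------


@dataclass
class AlignmentMatrix:
    """Binary indicators ``z_ij^u`` with ``i in -1..n1-1``, ``j in -1..n2-1``.

    Stored as a dense boolean array of shape ``(n1+1, n2+1, 5)``; array index
    0 on the first two axes corresponds to residue index ``-1``.
    """

    z: np.ndarray
    n1: int
    n2: int

    @property
    def n_ones(self) -> int:
        return int(self.z.sum())


def triples_to_matrix(a: Alignment) -> AlignmentMatrix:
    """Convert a valid alignment to its binary-variable representation."""
    a.validate()
    z = np.zeros((a.n1 + 1, a.n2 + 1, 5), dtype=bool)
    for i, j, u in a.triples:
        z[i + 1, j + 1, u] = True
    return AlignmentMatrix(z, a.n1, a.n2)


def matrix_to_triples(m: AlignmentMatrix) -> Alignment:
    """Reconstruct the (canonical) alignment from its binary variables.

    Raises :class:`AlignmentError` if the indicator set does not describe a
    single connected alignment path.
    """
    z = np.asarray(m.z, dtype=bool)
    if z.shape != (m.n1 + 1, m.n2 + 1, 5):
        raise AlignmentError("indicator array has wrong shape")
    triples = []
    for i1, j1, u in zip(*np.nonzero(z)):
        triples.append((int(i1) - 1, int(j1) - 1, AlignState(int(u))))
    if not triples:
        raise AlignmentError("empty indicator set (no match state)")
    # ordering is recovered by canonicalization; validity is fully re-checked
    head = [t for t in triples if t[2] == AlignState.GH]
    tail = [t for t in triples if t[2] == AlignState.GT]
    inner = sorted(
        [t for t in triples if t[2] not in (AlignState.GH, AlignState.GT)],
        key=lambda t: (max(t[0], -1 if t[0] < 0 else t[0]),),
    )
    # interleave M/Ix/Iy by consumption order: sort by (template idx if any,
    # query idx if any) using the fact that consumed indices are each a
    # permutation of 0..n-1
    inner = _order_interior(inner, m.n1, m.n2)
    a = Alignment(head + inner + tail, m.n1, m.n2)
    return a.canonicalize()


def _order_interior(inner, n1, n2):
    """Order interior M/Ix/Iy triples consistently with increasing indices."""
    ms = sorted([t for t in inner if t[2] == AlignState.M])
    xs = sorted([t for t in inner if t[2] == AlignState.IX])
    ys = sorted([t for t in inner if t[2] == AlignState.IY], key=lambda t: t[1])
    out = []
    for k, mtr in enumerate(ms):
        lo_i = ms[k - 1][0] if k else -1
        lo_j = ms[k - 1][1] if k else -1
        out.extend([t for t in xs if lo_i < t[0] < mtr[0]])
        out.extend([t for t in ys if lo_j < t[1] < mtr[1]])
        out.append(mtr)
    if ms:
        out.extend([t for t in xs if t[0] > ms[-1][0]])
        out.extend([t for t in ys if t[1] > ms[-1][1]])
    else:
        out.extend(xs + ys)
    return out


# ---------------------------------------------------------------------------
# aligned pairs and evaluation
# ---------------------------------------------------------------------------


def aligned_pairs(a: Alignment) -> set:
    """The set of ``(i, j)`` residue pairs aligned with state M."""
    a.validate()
    return {(i, j) for i, j, u in a.triples if u == AlignState.M}


@dataclass(frozen=True)
class AlignEvalResult:
    """Reference-dependent precision/recall of a predicted alignment."""

    precision: float
    recall: float
    n_pred_pairs: int
    n_ref_pairs: int
    n_correct: int


def evaluate_alignment(pred: Alignment, ref: Alignment) -> AlignEvalResult:
    """Precision/recall of ``pred`` against the reference alignment.

    Precision is the fraction of predicted aligned positions that occur in
    the reference; recall is the fraction of reference aligned positions
    recovered by the prediction.
    """
    if (pred.n1, pred.n2) != (ref.n1, ref.n2):
        raise AlignmentError("pred and ref describe different protein pairs")
    p, r = aligned_pairs(pred), aligned_pairs(ref)
    n_correct = len(p & r)
    return AlignEvalResult(
        precision=n_correct / len(p),
        recall=n_correct / len(r),
        n_pred_pairs=len(p),
        n_ref_pairs=len(r),
        n_correct=n_correct,
    )


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------


def _gapped_rows(a: Alignment, tseq: str, qseq: str):
    trow, qrow = [], []
    for i, j, _u in a.triples:
        trow.append(tseq[i] if i >= 0 else "-")
        qrow.append(qseq[j] if j >= 0 else "-")
    return "".join(trow), "".join(qrow)


def write_alignment_text(
    a: Alignment, tseq: str, qseq: str, header: str = ""
) -> str:
    """Serialize to the 3-line record: template row, query row, state string.

    An optional ``>`` header line (e.g. with score/logZ) precedes the record.
    """
    a.validate()
    if len(tseq) != a.n1 or len(qseq) != a.n2:
        raise AlignmentError("sequence lengths disagree with alignment")
    trow, qrow = _gapped_rows(a, tseq, qseq)
    head = f">{header}\n" if header else ">\n"
    return head + f"{trow}\n{qrow}\n{a.state_string()}\n"


def read_alignment_text(text: str):
    """Parse the 3-line record; returns ``(Alignment, tseq, qseq, header)``."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) != 4 or not lines[0].startswith(">"):
        raise AlignmentError("expected a header line plus a 3-line record")
    header, trow, qrow, states = lines[0][1:], lines[1], lines[2], lines[3]
    if not (len(trow) == len(qrow) == len(states)):
        raise AlignmentError("record rows have unequal length")
    triples, ti, qj = [], 0, 0
    for ct, cq, cs in zip(trow, qrow, states):
        if cs not in _CHAR_TO_STATE:
            raise AlignmentError(f"unknown state character {cs!r}")
        u = _CHAR_TO_STATE[cs]
        i = ti if ct != "-" else -1
        j = qj if cq != "-" else -1
        ti += ct != "-"
        qj += cq != "-"
        triples.append((i, j, u))
    a = Alignment(triples, ti, qj).validate()
    tseq = trow.replace("-", "")
    qseq = qrow.replace("-", "")
    return a, tseq, qseq, header


def state_string_to_alignment(s: str, n1: int, n2: int) -> Alignment:
    """Rebuild an alignment from a bare state string.

    The split of head/tail gap characters between the two proteins is inferred
    from the residue-count balance; when both head and tail gaps occur on both
    proteins this split is ambiguous and an error is raised (the 3-line text
    record is unambiguous and should be used instead).
    """
    n_m = s.count("M")
    n_x = s.count("X")
    n_y = s.count("Y")
    h = len(s) - len(s.lstrip("H"))
    t = len(s) - len(s.rstrip("T"))
    if s[h : len(s) - t].strip("MXY") != "" or s.count("H") != h or s.count("T") != t:
        raise AlignmentError("malformed state string")
    hx_tx = n1 - n_m - n_x  # template residues consumed by flank gaps
    hy_ty = n2 - n_m - n_y
    if hx_tx < 0 or hy_ty < 0 or hx_tx + hy_ty != h + t:
        raise AlignmentError("state string inconsistent with lengths")
    # head takes template-consuming gaps first (canonical order); the split is
    # unique unless both flanks could trade template for query consumption
    hx = min(h, hx_tx)
    tx = hx_tx - hx
    if tx > t or (h - hx) > hy_ty:
        raise AlignmentError("state string inconsistent with lengths")
    if 0 < hx < h and 0 < tx < t:
        raise AlignmentError("ambiguous flank-gap split; use the 3-line record")
    triples, ti, qj = [], 0, 0
    consume = [True] * hx + [False] * (h - hx)
    consume += [None] * (len(s) - h - t)
    consume += [True] * tx + [False] * (t - tx)
    for cs, cons in zip(s, consume):
        u = _CHAR_TO_STATE[cs]
        if u == AlignState.M:
            triples.append((ti, qj, u)); ti += 1; qj += 1
        elif u == AlignState.IX:
            triples.append((ti, -1, u)); ti += 1
        elif u == AlignState.IY:
            triples.append((-1, qj, u)); qj += 1
        elif cons:
            triples.append((ti, -1, u)); ti += 1
        else:
            triples.append((-1, qj, u)); qj += 1
    return Alignment(triples, n1, n2).validate()


def path_to_alignment(path: Sequence, states: Sequence, n1: int, n2: int) -> Alignment:
    """Rebuild an alignment from its lattice path and per-step states."""
    triples, prev = [], (0, 0)
    for (ti, qj), u in zip(path, states):
        di, dj = ti - prev[0], qj - prev[1]
        i = ti - 1 if di == 1 else -1
        j = qj - 1 if dj == 1 else -1
        triples.append((i, j, AlignState(u)))
        prev = (ti, qj)
    return Alignment(triples, n1, n2).validate()


def alignment_from_pairs(pairs, n1: int, n2: int) -> Alignment:
    """Build the canonical alignment realizing a set of aligned ``(i, j)``
    pairs: flank gaps outside the first/last pair, Ix-then-Iy runs between
    consecutive pairs."""
    pairs = sorted(set((int(i), int(j)) for i, j in pairs))
    if not pairs:
        raise AlignmentError("at least one aligned pair is required")
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        if i1 <= i0 or j1 <= j0:
            raise AlignmentError("aligned pairs must be strictly increasing")
    triples = []
    fi, fj = pairs[0]
    triples += [(i, -1, AlignState.GH) for i in range(fi)]
    triples += [(-1, j, AlignState.GH) for j in range(fj)]
    prev_i, prev_j = fi, fj
    triples.append((fi, fj, AlignState.M))
    for i, j in pairs[1:]:
        triples += [(k, -1, AlignState.IX) for k in range(prev_i + 1, i)]
        triples += [(-1, k, AlignState.IY) for k in range(prev_j + 1, j)]
        triples.append((i, j, AlignState.M))
        prev_i, prev_j = i, j
    triples += [(i, -1, AlignState.GT) for i in range(prev_i + 1, n1)]
    triples += [(-1, j, AlignState.GT) for j in range(prev_j + 1, n2)]
    return Alignment(triples, n1, n2).validate()


def write_alignment_a3m(a: Alignment, tseq: str, qseq: str,
                        tname: str = "template", qname: str = "query") -> str:
    """Pairwise FASTA export with '-' gaps (A3M-style, no insert lowercase)."""
    trow, qrow = _gapped_rows(a.validate(), tseq, qseq)
    return f">{tname}\n{trow}\n>{qname}\n{qrow}\n"
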