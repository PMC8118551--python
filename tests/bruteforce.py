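"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the alignment-path rules (start in
a head gap or a match, end in a match or a tail gap, per-state residue
consumption, canonical gap ordering) without calling the package's dynamic
programs, so it can serve as an exhaustive oracle on tiny instances.
"""

import itertools

import numpy as np

from crfthread.alignment import Alignment, AlignState

# internal states: M, Ix, Iy, GhX, GhY, GtX, GtY
CONSUME = [(1, 1), (1, 0), (0, 1), (1, 0), (0, 1), (1, 0), (0, 1)]
COLLAPSE = [0, 1, 2, 3, 3, 4, 4]
START = (0, 3, 4)
END = (0, 5, 6)


def default_internal_feasible():
    allowed = {
        (0, 0), (0, 1), (0, 2), (0, 5), (0, 6),   # M -> M, Ix, Iy, Gt*
        (1, 0), (1, 1), (1, 2),                   # Ix -> M, Ix, Iy
        (2, 0), (2, 2),                           # Iy -> M, Iy
        (3, 0), (3, 3), (3, 4), (4, 0), (4, 4),   # Gh* -> M, Gh* (no Y->X)
        (5, 5), (5, 6), (6, 6),                   # Gt* -> Gt* (no Y->X)
    }
    return allowed


def enumerate_paths(n1, n2, allowed=None):
    """All internal-state sequences describing a valid alignment."""
    allowed = allowed or default_internal_feasible()
    out = []

    def rec(i, j, path):
        if i == n1 and j == n2 and path and path[-1] in END:
            out.append(tuple(path))
        if i > n1 or j > n2:
            return
        for s in range(7):
            if path:
                if (path[-1], s) not in allowed:
                    continue
            elif s not in START:
                continue
            di, dj = CONSUME[s]
            if i + di <= n1 and j + dj <= n2:
                path.append(s)
                rec(i + di, j + dj, path)
                path.pop()

    rec(0, 0, [])
    return out


def path_to_alignment(path, n1, n2):
    triples, i, j = [], 0, 0
    for s in path:
        di, dj = CONSUME[s]
        triples.append((i if di else -1, j if dj else -1, AlignState(COLLAPSE[s])))
        i, j = i + di, j + dj
    return Alignment(triples, n1, n2)


def enumerate_alignments(n1, n2):
    return [path_to_alignment(p, n1, n2) for p in enumerate_paths(n1, n2)]


def path_score(path, theta, tscore5=None):
    """Emission + transition score of an internal path, computed directly."""
    theta = np.asarray(theta, float)
    total, i, j, prev = 0.0, 0, 0, None
    for s in path:
        di, dj = CONSUME[s]
        i, j = i + di, j + dj
        ii = i - 1 if di else max(i - 1, 0)
        jj = j - 1 if dj else max(j - 1, 0)
        total += theta[ii, jj, COLLAPSE[s]]
        if prev is not None and tscore5 is not None:
            total += tscore5[COLLAPSE[prev], COLLAPSE[s]]
        prev = s
    return total


def path_match_pairs(path):
    pairs, i, j = set(), 0, 0
    for s in path:
        di, dj = CONSUME[s]
        i, j = i + di, j + dj
        if s == 0:
            pairs.add((i - 1, j - 1))
    return pairs


def brute_force_crf(n1, n2, theta, tscore5=None):
    """Viterbi optimum, logZ and match marginals by exhaustive enumeration."""
    paths = enumerate_paths(n1, n2)
    scores = np.array([path_score(p, theta, tscore5) for p in paths])
    m = scores.max()
    logZ = m + np.log(np.exp(scores - m).sum())
    weights = np.exp(scores - logZ)
    marg = np.zeros((n1, n2))
    for p, wgt in zip(paths, weights):
        for (i, j) in path_match_pairs(p):
            marg[i, j] += wgt
    return {
        "paths": paths,
        "scores": scores,
        "viterbi": float(m),
        "logZ": float(logZ),
        "marginals": marg,
    }


def eq1_objective(pairs, theta, u_pot, tbins, w=1.0, singleton=None):
    """Direct Eq-style objective for a set of aligned pairs.

    ``singleton`` overrides the singleton part (e.g. full path emissions);
    by default only match emissions are summed, which is exact when gap
    emissions are zero.
    """
    pairs = sorted(pairs)
    s1 = singleton
    if s1 is None:
        s1 = sum(theta[i, j, 0] for i, j in pairs)
    s2 = 0.0
    for (i, j), (k, l) in itertools.combinations(pairs, 2):
        b = int(tbins[i, k])
        if b < u_pot.shape[2] - 1:
            s2 += -u_pot[j, l, b]
    return w * s1 + s2
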