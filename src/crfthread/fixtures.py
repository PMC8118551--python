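"""Synthetic toy folds and query/template pairs with known references.

Real threading benchmarks need solved structures, sequence profiles from
large MSAs and a trained distance predictor.  This module emulates the whole
setup at toy scale so every component is testable end to end:

* :func:`sample_fold` draws a self-avoiding, persistence-biased random chain
  with consecutive Cbeta-like spacing of ~3.8 Angstrom and a pull toward its
  centroid so that non-local contacts (< 16 Angstrom) exist.
* :func:`make_pair` treats the fold as the template, derives the query by
  point mutations and single-residue indels, and records the generative
  correspondence as the reference alignment.  Query-side "predictions"
  (profile, secondary structure, accessibility, distance distribution) are
  the ground truth blended toward uniform by a ``noise`` parameter, which
  models predictor error; at ``noise = 0`` the distance distribution is
  one-hot at the query's true self-distance bins.
* :func:`make_dataset` draws a reproducible corpus at four difficulty levels
  (mutation/indel rates) mixed 1:2:2:1, emphasizing medium difficulty, with
  a train/validation/test split that never shares a fold across splits.

What this generator does *not* emulate: real backbone geometry and secondary
structure, profile statistics of deep MSAs, and structurally divergent
homologs whose reference alignment is itself uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, alignment_from_pairs
from .distance import DistanceBins, DistanceDistribution, N_BINS
from .features import (
    AA_ALPHABET,
    QueryRecord,
    TemplateRecord,
    acc_class,
    one_hot_sequence,
    profile_log_odds,
)

__all__ = ["ToyFold", "PairFixture", "sample_fold", "make_pair", "make_dataset"]

_BOND_MIN, _BOND_MAX = 3.6, 4.0
_CLASH = 3.5


@dataclass(frozen=True)
class ToyFold:
    """A compact self-avoiding chain of Cbeta-like coordinates."""

    coords: np.ndarray
    seed: int

    def __len__(self):
        return len(self.coords)


def _try_walk(n: int, rng: np.random.Generator):
    coords = np.zeros((n, 3))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    for k in range(1, n):
        prev = coords[k - 1]
        centroid = coords[:k].mean(axis=0)
        placed = False
        for _ in range(60):
            pull = centroid - prev
            norm = np.linalg.norm(pull)
            pull = pull / norm if norm > 1e-9 else 0.0
            cand = 0.55 * d + 0.9 * rng.normal(size=3) + 0.45 * pull
            cand /= np.linalg.norm(cand)
            step = rng.uniform(_BOND_MIN + 0.1, _BOND_MAX - 0.1)
            pos = prev + cand * step
            if k < 2 or np.linalg.norm(pos - coords[: k - 1], axis=1).min() >= _CLASH + 0.05:
                coords[k] = pos
                d = cand
                placed = True
                break
        if not placed:
            return None
    return coords


def sample_fold(n: int, seed: int) -> ToyFold:
    """Deterministically sample a toy fold of ``n`` residues."""
    if n < 2:
        raise ValueError("a fold needs at least 2 residues")
    rng = np.random.default_rng(seed)
    for _attempt in range(200):
        coords = _try_walk(n, rng)
        if coords is not None:
            return ToyFold(coords, seed)
    raise RuntimeError(f"could not place a self-avoiding chain of length {n}")


def _geometry_ss3(coords: np.ndarray) -> np.ndarray:
    """Coarse secondary-structure labels from the i..i+3 distance."""
    n = len(coords)
    ss3 = np.full(n, 2, dtype=np.int64)  # C
    for i in range(n - 3):
        d3 = np.linalg.norm(coords[i] - coords[i + 3])
        if d3 < 7.5:
            ss3[i] = 0  # H
        elif d3 > 10.5:
            ss3[i] = 1  # E
    return ss3


_SS3_TO_SS8 = np.array([0, 3, 7])  # H->H, E->E, C->L


def _geometry_acc(dist: np.ndarray) -> np.ndarray:
    """Relative accessibility from the 8-Angstrom neighbor count."""
    nb = (dist < 8.0).sum(axis=1) - 1
    return np.clip(1.0 - nb / 12.0, 0.0, 1.0)


def _noisy_onehot(labels, n_classes, noise):
    out = np.full((len(labels), n_classes), noise / n_classes)
    out[np.arange(len(labels)), labels] += 1.0 - noise
    return out


@dataclass
class PairFixture:
    """One synthetic query/template pair with its generative ground truth."""

    query: QueryRecord
    template: TemplateRecord
    reference: Alignment
    dist_pred: DistanceDistribution
    mutation_rate: float
    indel_rate: float
    noise: float
    seed: int
    fold_id: int = 0


def make_pair(
    fold: ToyFold,
    mutation_rate: float = 0.2,
    indel_rate: float = 0.1,
    noise: float = 0.1,
    seed: int = 0,
    style: str = "A",
) -> PairFixture:
    """Derive a query from a template fold; the correspondence is the
    reference alignment.

    ``style`` selects the reference convention: "A" keeps every generative
    aligned pair; "B" trims the first and last aligned pair (when more than
    four exist), emulating a reference builder that discards low-confidence
    flanks.
    """
    if not (0 <= mutation_rate < 1 and 0 <= indel_rate < 1 and 0 <= noise < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n1 = len(fold)
    aas = np.array(list(AA_ALPHABET))
    tseq = "".join(rng.choice(aas, size=n1))
    dist = np.linalg.norm(fold.coords[:, None] - fold.coords[None, :], axis=2)
    ss3 = _geometry_ss3(fold.coords)
    acc = _geometry_acc(dist)
    template = TemplateRecord(
        sequence=tseq,
        coords_cb=fold.coords,
        ss3=ss3,
        ss8=_SS3_TO_SS8[ss3],
        acc=acc,
        name=f"fold{fold.seed}",
    )

    deleted = rng.random(n1) < indel_rate / 2.0
    if deleted.all():
        raise ValueError("degenerate pair: every template residue deleted")
    ins_after = rng.random(n1 + 1) < indel_rate / 2.0  # slot k = before residue k
    qseq, qcoords, qlab3, qacc_cls, pairs = [], [], [], [], []
    for i in range(n1 + 1):
        if ins_after[i]:
            qseq.append(str(rng.choice(aas)))
            qcoords.append(np.full(3, np.nan))
            qlab3.append(2)
            qacc_cls.append(2)
        if i == n1 or deleted[i]:
            continue
        c = tseq[i]
        if rng.random() < mutation_rate:
            c = str(rng.choice(aas[aas != c]))
        pairs.append((i, len(qseq)))
        qseq.append(c)
        qcoords.append(fold.coords[i])
        qlab3.append(int(ss3[i]))
        qacc_cls.append(acc_class(acc[i]))
    if style == "B" and len(pairs) > 4:
        pairs = pairs[1:-1]
    elif style not in ("A", "B"):
        raise ValueError(f"unknown reference style {style!r}")
    n2 = len(qseq)
    reference = alignment_from_pairs(pairs, n1, n2)

    qseq = "".join(qseq)
    psfm = (1.0 - noise) * one_hot_sequence(qseq) + noise / 20.0
    query = QueryRecord(
        sequence=qseq,
        psfm=psfm,
        pssm=profile_log_odds(psfm),
        ss3=_noisy_onehot(qlab3, 3, noise),
        ss8=_noisy_onehot(_SS3_TO_SS8[np.array(qlab3)], 8, noise),
        acc=_noisy_onehot(qacc_cls, 3, noise),
        name=f"query{fold.seed}-{seed}",
    )

    qcoords = np.asarray(qcoords)
    bins = DistanceBins()
    p = np.full((n2, n2, N_BINS), 1.0 / N_BINS)
    known = np.isfinite(qcoords).all(axis=1)
    for j in range(n2):
        for l in range(j + 1, n2):
            if known[j] and known[l]:
                b = bins.discretize(float(np.linalg.norm(qcoords[j] - qcoords[l])))
                row = np.full(N_BINS, noise / N_BINS)
                row[b] += 1.0 - noise
                p[j, l] = p[l, j] = row
    dist_pred = DistanceDistribution(p)
    return PairFixture(
        query=query,
        template=template,
        reference=reference,
        dist_pred=dist_pred,
        mutation_rate=mutation_rate,
        indel_rate=indel_rate,
        noise=noise,
        seed=seed,
        fold_id=fold.seed,
    )


#: difficulty ladder (mutation_rate, indel_rate), easy to hard; sampled 1:2:2:1
DIFFICULTY_LEVELS = ((0.10, 0.04), (0.30, 0.08), (0.45, 0.12), (0.60, 0.16))
_LEVEL_CYCLE = (0, 1, 1, 2, 2, 3)


def make_dataset(
    n_pairs: int,
    length_range=(12, 20),
    noise: float = 0.1,
    seed: int = 0,
    split=(0.6, 0.2, 0.2),
):
    """Reproducible corpus of fixtures split train/validation/test by fold.

    Each pair uses its own fold, so no fold crosses a split boundary.
    Difficulty levels cycle through :data:`DIFFICULTY_LEVELS` in the ratio
    1:2:2:1.  Returns ``{"train": [...], "val": [...], "test": [...]}``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    fixtures = []
    for k in range(n_pairs):
        mut, ind = DIFFICULTY_LEVELS[_LEVEL_CYCLE[k % len(_LEVEL_CYCLE)]]
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        fold_seed = int(rng.integers(0, 2**31 - 1))
        fold = sample_fold(n, fold_seed)
        fixtures.append(
            make_pair(fold, mut, ind, noise, seed=int(rng.integers(0, 2**31 - 1)))
        )
    n_train = int(round(split[0] * n_pairs))
    n_val = int(round(split[1] * n_pairs))
    return {
        "train": fixtures[:n_train],
        "val": fixtures[n_train : n_train + n_val],
        "test": fixtures[n_train + n_val :],
    }
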