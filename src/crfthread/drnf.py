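"""Emission scorers and maximum-likelihood training.

Two scorers produce the CRF emission table ``theta_ij^u``:

* :class:`LinearScorer` -- an affine function of the nine pairwise feature
  channels for the match state, with constant insertion penalties.  Fast,
  convex, and the workhorse for desk-scale experiments.
* :class:`DrnfScorer` -- the deep scorer: a 1D residual convolutional network
  per protein extracts sequential context, outer concatenation lifts the two
  1D feature maps to the pairwise grid, and a 2D residual network (together
  with the raw pairwise channels) emits the match score.  Insertion scores
  are either learned scalars (default) or two extra output channels.

Both scorers are trained by maximum likelihood: the gradient of the CRF
reference log-likelihood with respect to ``theta`` (observed minus expected
emission counts, from forward-backward) is backpropagated through the scorer.
Training pairs are grouped into minibatches by their length product
``n1 * n2`` so each batch does a comparable amount of work.

The module also builds the input of the distance-aware alignment refiner:
an initial-alignment indicator, the match emission scores, and a pairwise
distance-potential channel that sums the pair scores ``theta_ijkl`` over the
initial alignment's aligned pairs ``(k, l)`` whose template residue *k* lies
within 16 Angstrom of *i*.  A 2D residual network over those three channels
re-emits match scores which can be decoded into an improved alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, aligned_pairs
from .crf import ScoreTable, TransitionModel, loglik_grad_theta
from .distance import DistancePotential
from .features import (
    PairFeatureTensor,
    QueryRecord,
    TemplateRecord,
    pair_features,
    query_seq_features,
    template_seq_features,
)
from . import nn

__all__ = [
    "DrnfConfig",
    "LinearScorer",
    "DrnfScorer",
    "RefinerScorer",
    "RefinerInput",
    "build_refiner_input",
    "train_mle",
]


@dataclass
class DrnfConfig:
    """Architecture of the deep scorer; defaults follow the published depths
    (ten 1D convolutions of kernel 3; twenty 2D residual blocks of three
    5x5 convolutions).  Channel widths are our own defaults."""

    conv1d_layers: int = 10
    kernel1d: int = 3
    res2d_blocks: int = 20
    convs_per_block: int = 3
    kernel2d: int = 5
    width1d: int = 32
    width2d: int = 64
    emit_gap_scores: bool = False
    use_norm: bool = True


class LinearScorer(nn.Module):
    """theta_ij^M = <w, features(i, j)> + bias; constant Ix/Iy penalties."""

    _params = ("w", "bias", "gap")

    def __init__(self, n_channels: int = 9, gap_ix: float = 0.0,
                 gap_iy: float = 0.0):
        self.w = nn.Param(np.zeros(n_channels))
        self.bias = nn.Param(np.zeros(1))
        self.gap = nn.Param(np.array([gap_ix, gap_iy]))

    def score_features(self, feats: PairFeatureTensor) -> ScoreTable:
        f = feats.channels
        if f.shape[2] != self.w.value.shape[0]:
            raise ValueError("feature channel count does not match weights")
        th = np.zeros((f.shape[0], f.shape[1], 5))
        th[:, :, 0] = f @ self.w.value + self.bias.value[0]
        th[:, :, 1] = self.gap.value[0]
        th[:, :, 2] = self.gap.value[1]
        return ScoreTable(th)

    def score(self, q: QueryRecord, t: TemplateRecord) -> ScoreTable:
        return self.score_features(pair_features(q, t))

    def score_and_cache(self, q: QueryRecord, t: TemplateRecord):
        feats = pair_features(q, t)
        return self.score_features(feats), feats

    def backward(self, cache: PairFeatureTensor, dtheta: np.ndarray) -> None:
        f = cache.channels
        self.w.grad += np.einsum("ijc,ij->c", f, dtheta[:, :, 0])
        self.bias.grad += dtheta[:, :, 0].sum()
        self.gap.grad += [dtheta[:, :, 1].sum(), dtheta[:, :, 2].sum()]


class DrnfScorer(nn.Module):
    """Deep convolutional residual neural field emission scorer."""

    _children = ("net1d_t", "net1d_q", "net2d")
    _params = ("gap",)

    def __init__(self, config: DrnfConfig | None = None, seed: int = 0,
                 in1d: int = 54, n_pair: int = 9):
        cfg = config or DrnfConfig()
        self.config = cfg
        rng = np.random.default_rng(seed)
        self.net1d_t = nn.conv_stack(
            nn.Conv1D, in1d, cfg.width1d, cfg.kernel1d, cfg.conv1d_layers,
            rng, cfg.use_norm)
        self.net1d_q = nn.conv_stack(
            nn.Conv1D, in1d, cfg.width1d, cfg.kernel1d, cfg.conv1d_layers,
            rng, cfg.use_norm)
        out_ch = 3 if cfg.emit_gap_scores else 1
        self.net2d = nn.residual_net2d(
            2 * cfg.width1d + n_pair, cfg.width2d, cfg.kernel2d,
            cfg.res2d_blocks, cfg.convs_per_block, out_ch, rng, cfg.use_norm)
        self.gap = nn.Param(np.zeros(2))

    def _forward(self, q: QueryRecord, t: TemplateRecord):
        ft = self.net1d_t.forward(template_seq_features(t))  # (n1, w)
        fq = self.net1d_q.forward(query_seq_features(q))  # (n2, w)
        pf = pair_features(q, t).channels
        n1, n2, w = ft.shape[0], fq.shape[0], ft.shape[1]
        # outer concatenation: broadcast each protein's 1D map over the grid
        x2d = np.concatenate(
            [
                np.broadcast_to(ft[:, None, :], (n1, n2, w)),
                np.broadcast_to(fq[None, :, :], (n1, n2, w)),
                pf,
            ],
            axis=2,
        )
        out = self.net2d.forward(x2d)
        th = np.zeros((n1, n2, 5))
        th[:, :, 0] = out[:, :, 0]
        if self.config.emit_gap_scores:
            th[:, :, 1] = out[:, :, 1]
            th[:, :, 2] = out[:, :, 2]
        else:
            th[:, :, 1] = self.gap.value[0]
            th[:, :, 2] = self.gap.value[1]
        if not np.isfinite(th).all():
            raise FloatingPointError("non-finite activations in scorer")
        return ScoreTable(th), w

    def score(self, q: QueryRecord, t: TemplateRecord) -> ScoreTable:
        return self._forward(q, t)[0]

    def score_and_cache(self, q, t):
        table, w = self._forward(q, t)
        return table, w

    def backward(self, cache, dtheta: np.ndarray) -> None:
        w = cache
        out_ch = 3 if self.config.emit_gap_scores else 1
        dout = np.zeros(dtheta.shape[:2] + (out_ch,))
        dout[:, :, 0] = dtheta[:, :, 0]
        if self.config.emit_gap_scores:
            dout[:, :, 1] = dtheta[:, :, 1]
            dout[:, :, 2] = dtheta[:, :, 2]
        else:
            self.gap.grad += [dtheta[:, :, 1].sum(), dtheta[:, :, 2].sum()]
        dx2d = self.net2d.backward(dout)
        self.net1d_t.backward(dx2d[:, :, :w].sum(axis=1))
        self.net1d_q.backward(dx2d[:, :, w : 2 * w].sum(axis=0))


# ---------------------------------------------------------------------------
# maximum-likelihood training
# ---------------------------------------------------------------------------


def _length_product_batches(pairs, budget):
    """Group training pairs into minibatches whose total ``n1 * n2`` stays
    within ``budget`` (each batch holds at least one pair)."""
    order = sorted(range(len(pairs)), key=lambda k: len(pairs[k][1]) * len(pairs[k][0]))
    batches, cur, load = [], [], 0
    for k in order:
        q, t = pairs[k][0], pairs[k][1]
        size = len(q) * len(t)
        if cur and load + size > budget:
            batches.append(cur)
            cur, load = [], 0
        cur.append(k)
        load += size
    if cur:
        batches.append(cur)
    return batches


def train_mle(
    pairs,
    scorer=None,
    epochs: int = 10,
    lr: float = 0.05,
    batch_budget: int = 4096,
    seed: int = 0,
    tm: TransitionModel | None = None,
    optimizer: str = "adam",
):
    """Fit a scorer by maximizing the reference-alignment log-likelihood.

    ``pairs`` is a list of ``(QueryRecord, TemplateRecord, Alignment)``.
    The state transition matrix is held fixed.  Returns ``(scorer, history)``
    where ``history`` is the mean per-pair log-likelihood recorded at each
    epoch.  Raises if the loss turns non-finite.
    """
    scorer = scorer if scorer is not None else LinearScorer()
    tm = tm or TransitionModel()
    for _q, _t, ref in pairs:
        ref.validate()
    rng = np.random.default_rng(seed)
    if optimizer == "adam":
        opt = nn.Adam(scorer, lr=lr)
    elif optimizer == "sgd":
        opt = nn.SGD(scorer, lr=lr)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    history = []
    for _epoch in range(epochs):
        batches = _length_product_batches(pairs, batch_budget)
        rng.shuffle(batches)
        total_ll = 0.0
        for batch in batches:
            scorer.zero_grad()
            for k in batch:
                q, t, ref = pairs[k]
                theta, cache = scorer.score_and_cache(q, t)
                ll, g = loglik_grad_theta(ref, theta, tm)
                if not np.isfinite(ll):
                    raise FloatingPointError("log-likelihood diverged")
                total_ll += ll
                scorer.backward(cache, -g / len(batch))  # minimize -loglik
            opt.step()
        history.append(total_ll / len(pairs))
    return scorer, history


# ---------------------------------------------------------------------------
# distance-aware refiner
# ---------------------------------------------------------------------------


@dataclass
class RefinerInput:
    """Three pairwise channels: initial-alignment indicator, match emission
    scores, and the summed distance-potential score."""

    channels: np.ndarray  # (n1, n2, 3)


def build_refiner_input(
    init: Alignment,
    theta,
    pot: DistancePotential,
    tbins,
    tdist=None,
    cutoff: float = 16.0,
) -> RefinerInput:
    """Assemble the refiner's input channels from an initial alignment.

    The potential channel at ``(i, j)`` sums ``theta_ijkl = -u(j, l, b(i,k))``
    over the initial alignment's aligned pairs ``(k, l)`` with ``k != i``,
    ``l != j`` and template distance ``d(i, k) < cutoff`` (equivalently, a
    bin below the last).  ``tdist`` optionally supplies the raw distance
    matrix; otherwise the bin matrix provides the cutoff test.
    """
    init.validate()
    th = theta.theta if isinstance(theta, ScoreTable) else np.asarray(theta)
    u = pot.u if isinstance(pot, DistancePotential) else np.asarray(pot)
    tb = np.asarray(tbins)
    n1, n2 = th.shape[:2]
    chans = np.zeros((n1, n2, 3))
    chans[:, :, 1] = th[:, :, 0]
    pair_list = sorted(aligned_pairs(init))
    for (k, l) in pair_list:
        chans[k, l, 0] = 1.0
        b = tb[:, k]
        if tdist is not None:
            within = np.asarray(tdist)[:, k] < cutoff
        else:
            within = b < u.shape[2] - 1
        contrib = -u[:, l, :][:, b].T  # (n1, n2): contrib[i, j] = -u[j, l, b[i]]
        contrib = np.where(within[:, None], contrib, 0.0)
        contrib[k, :] = 0.0  # self template position excluded
        contrib[:, l] = 0.0  # self query position excluded
        chans[:, :, 2] += contrib
    return RefinerInput(chans)


def save_checkpoint(path, scorer) -> None:
    """Write scorer parameters as an ``.npz`` with a JSON config sidecar."""
    import dataclasses
    import json

    arrays = {name: p.value for name, p in scorer.parameters()}
    np.savez(path, **arrays)
    meta = {"type": type(scorer).__name__}
    if isinstance(scorer, (DrnfScorer, RefinerScorer)):
        meta["config"] = dataclasses.asdict(scorer.config)
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_checkpoint(path):
    """Rebuild a scorer saved by :func:`save_checkpoint`."""
    import json

    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    if meta["type"] == "LinearScorer":
        scorer = LinearScorer()
    elif meta["type"] == "DrnfScorer":
        scorer = DrnfScorer(DrnfConfig(**meta["config"]))
    elif meta["type"] == "RefinerScorer":
        scorer = RefinerScorer(DrnfConfig(**meta["config"]))
    else:
        raise ValueError(f"unknown scorer type {meta['type']!r}")
    with np.load(path) as data:
        for name, p in scorer.parameters():
            p.value[...] = data[name]
    return scorer


class RefinerScorer(nn.Module):
    """2D residual network emitting refined match scores from a
    :class:`RefinerInput`; decoded with Viterbi like any emission table."""

    _children = ("net2d",)
    _params = ("gap",)

    def __init__(self, config: DrnfConfig | None = None, seed: int = 0):
        cfg = config or DrnfConfig()
        self.config = cfg
        rng = np.random.default_rng(seed)
        self.net2d = nn.residual_net2d(
            3, cfg.width2d, cfg.kernel2d, cfg.res2d_blocks,
            cfg.convs_per_block, 1, rng, cfg.use_norm)
        self.gap = nn.Param(np.zeros(2))

    def score(self, rin: RefinerInput) -> ScoreTable:
        out = self.net2d.forward(rin.channels)
        n1, n2 = out.shape[:2]
        th = np.zeros((n1, n2, 5))
        th[:, :, 0] = out[:, :, 0]
        th[:, :, 1] = self.gap.value[0]
        th[:, :, 2] = self.gap.value[1]
        if not np.isfinite(th).all():
            raise FloatingPointError("non-finite activations in refiner")
        return ScoreTable(th)

    def score_and_cache(self, rin: RefinerInput):
        return self.score(rin), None

    def backward(self, cache, dtheta: np.ndarray) -> None:
        dout = dtheta[:, :, :1].copy()
        self.gap.grad += [dtheta[:, :, 1].sum(), dtheta[:, :, 2].sum()]
        self.net2d.backward(dout)
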