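"""Query/template records, file IO and pairwise sequential features.

The query side carries predicted per-position information (sequence profile
PSFM/PSSM, 3- and 8-class secondary-structure probabilities, 3-class solvent
accessibility probabilities); the template side carries observed structure
(Cbeta coordinates -- Calpha for glycine -- secondary-structure labels,
relative solvent accessibility and the derived Cbeta-Cbeta distance matrix).

``pair_features`` builds the nine named pairwise channels consumed by the
emission scorers: amino-acid identity, BLOSUM80/62/45 substitution scores,
profile inner products in both directions (query PSFM x template PSSM and
template PSFM x query PSSM), and agreement scores for secondary structure
(3- and 8-class) and solvent accessibility, each defined as the probability
the query's prediction assigns to the template's observed class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq3

__all__ = [
    "AA_ALPHABET",
    "QueryRecord",
    "TemplateRecord",
    "PairFeatureTensor",
    "PAIR_CHANNELS",
    "pair_features",
    "query_seq_features",
    "template_seq_features",
    "read_query",
    "write_query",
    "read_template",
    "write_template",
    "save_distance_distribution",
    "load_distance_distribution",
    "acc_class",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: k for k, a in enumerate(AA_ALPHABET)}
SS3_CLASSES = "HEC"
SS8_CLASSES = "HGIEBTSL"
#: relative-accessibility thresholds separating buried / intermediate / exposed
ACC_THRESHOLDS = (0.10, 0.40)

PAIR_CHANNELS = (
    "identity",
    "blosum80",
    "blosum62",
    "blosum45",
    "prof_q2t",
    "prof_t2q",
    "ss3_score",
    "ss8_score",
    "acc_score",
)


class ParseError(ValueError):
    """Raised when an input file fails validation."""


def aa_index(c: str) -> int:
    """0..19 for the standard residues, -1 for 'X' (unknown)."""
    if c in _AA_INDEX:
        return _AA_INDEX[c]
    if c == "X":
        return -1
    raise ParseError(f"unknown residue code {c!r}")


def _blosum_lookup(name: str) -> np.ndarray:
    """(21, 21) score table over AA_ALPHABET + X; X rows/cols are 0."""
    mat = substitution_matrices.load(name)
    out = np.zeros((21, 21))
    for a in range(20):
        for b in range(20):
            out[a, b] = mat[AA_ALPHABET[a], AA_ALPHABET[b]]
    return out


_BLOSUM = {n: _blosum_lookup(f"BLOSUM{n}") for n in (80, 62, 45)}


def acc_class(rel_acc: float) -> int:
    """Discretize relative solvent accessibility into 3 classes."""
    return int(rel_acc >= ACC_THRESHOLDS[0]) + int(rel_acc >= ACC_THRESHOLDS[1])


def _check_rows(name, arr, length, width, normalized):
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape != (length, width):
        raise ParseError(f"{name} must have shape ({length}, {width})")
    if not np.isfinite(arr).all():
        raise ParseError(f"{name} contains non-finite values")
    if normalized and (np.abs(arr.sum(axis=1) - 1.0) > 1e-6).any():
        raise ParseError(f"{name} rows must sum to 1")
    return arr


@dataclass
class QueryRecord:
    """Predicted per-position inputs for the protein being modeled."""

    sequence: str
    psfm: np.ndarray
    pssm: np.ndarray
    ss3: np.ndarray
    ss8: np.ndarray
    acc: np.ndarray
    name: str = "query"

    def __post_init__(self):
        n = len(self.sequence)
        for c in self.sequence:
            aa_index(c)
        self.psfm = _check_rows("psfm", self.psfm, n, 20, True)
        self.pssm = _check_rows("pssm", self.pssm, n, 20, False)
        self.ss3 = _check_rows("ss3", self.ss3, n, 3, True)
        self.ss8 = _check_rows("ss8", self.ss8, n, 8, True)
        self.acc = _check_rows("acc", self.acc, n, 3, True)

    def __len__(self):
        return len(self.sequence)


@dataclass
class TemplateRecord:
    """Observed structure of the solved-structure protein."""

    sequence: str
    coords_cb: np.ndarray
    ss3: np.ndarray  # class indices into SS3_CLASSES
    ss8: np.ndarray  # class indices into SS8_CLASSES
    acc: np.ndarray  # relative solvent accessibility in [0, 1]
    name: str = "template"
    psfm: np.ndarray = None
    pssm: np.ndarray = None
    dist: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.sequence)
        for c in self.sequence:
            aa_index(c)
        self.coords_cb = np.asarray(self.coords_cb, dtype=np.float64)
        if self.coords_cb.shape != (n, 3) or not np.isfinite(self.coords_cb).all():
            raise ParseError("coords_cb must be a finite (n, 3) array")
        self.ss3 = np.asarray(self.ss3, dtype=np.int64)
        self.ss8 = np.asarray(self.ss8, dtype=np.int64)
        self.acc = np.asarray(self.acc, dtype=np.float64)
        if self.ss3.shape != (n,) or self.ss3.min(initial=0) < 0 or self.ss3.max(initial=0) > 2:
            raise ParseError("ss3 must be class indices 0..2")
        if self.ss8.shape != (n,) or self.ss8.min(initial=0) < 0 or self.ss8.max(initial=0) > 7:
            raise ParseError("ss8 must be class indices 0..7")
        if self.acc.shape != (n,) or (self.acc < 0).any() or (self.acc > 1).any():
            raise ParseError("acc must be relative accessibility in [0, 1]")
        d = np.linalg.norm(
            self.coords_cb[:, None, :] - self.coords_cb[None, :, :], axis=2
        )
        if self.dist is not None and np.abs(np.asarray(self.dist) - d).max() > 1e-6:
            raise ParseError("dist disagrees with coordinates")
        self.dist = d
        # profile defaults: one-hot PSFM, log-odds PSSM of the smoothed PSFM
        if self.psfm is None:
            self.psfm = one_hot_sequence(self.sequence)
        self.psfm = _check_rows("template psfm", self.psfm, n, 20, False)
        if self.pssm is None:
            self.pssm = profile_log_odds(self.psfm)
        self.pssm = _check_rows("template pssm", self.pssm, n, 20, False)

    def __len__(self):
        return len(self.sequence)


def one_hot_sequence(seq: str) -> np.ndarray:
    out = np.zeros((len(seq), 20))
    for k, c in enumerate(seq):
        idx = aa_index(c)
        if idx >= 0:
            out[k, idx] = 1.0
    return out


def profile_log_odds(psfm: np.ndarray, blend: float = 0.1) -> np.ndarray:
    """Log2 odds against the uniform background, after blending the profile
    with the background to keep the scores finite."""
    p = np.asarray(psfm, float) * (1.0 - blend) + blend / 20.0
    return np.log2(p / 0.05)


# ---------------------------------------------------------------------------
# pairwise features
# ---------------------------------------------------------------------------


@dataclass
class PairFeatureTensor:
    """Named feature channels on the (template, query) position grid."""

    channels: np.ndarray  # (n1, n2, 9)
    names: tuple = PAIR_CHANNELS

    @property
    def n1(self):
        return self.channels.shape[0]

    @property
    def n2(self):
        return self.channels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[:, :, self.names.index(name)]


def pair_features(q: QueryRecord, t: TemplateRecord) -> PairFeatureTensor:
    """Build the nine sequential-feature channels for a query/template pair."""
    n1, n2 = len(t), len(q)
    ti = np.array([aa_index(c) for c in t.sequence])
    qi = np.array([aa_index(c) for c in q.sequence])
    out = np.zeros((n1, n2, len(PAIR_CHANNELS)))
    known = (ti[:, None] >= 0) & (qi[None, :] >= 0)
    out[:, :, 0] = known & (ti[:, None] == qi[None, :])
    for c, nname in enumerate((80, 62, 45), start=1):
        out[:, :, c] = _BLOSUM[nname][ti[:, None], qi[None, :]] * known
    out[:, :, 3 + 1] = t.pssm @ q.psfm.T  # prof_q2t: <q.psfm[j], t.pssm[i]>
    out[:, :, 5] = t.psfm @ q.pssm.T  # prof_t2q
    out[:, :, 6] = q.ss3[:, t.ss3].T
    out[:, :, 7] = q.ss8[:, t.ss8].T
    t_acc_cls = np.array([acc_class(v) for v in t.acc])
    out[:, :, 8] = q.acc[:, t_acc_cls].T
    return PairFeatureTensor(out)


def query_seq_features(q: QueryRecord) -> np.ndarray:
    """Per-position input to the query 1D network: (n2, 54)."""
    return np.concatenate([q.psfm, q.pssm, q.ss3, q.ss8, q.acc], axis=1)


def template_seq_features(t: TemplateRecord) -> np.ndarray:
    """Per-position input to the template 1D network: (n1, 54)."""
    n = len(t)
    ss3 = np.eye(3)[t.ss3]
    ss8 = np.eye(8)[t.ss8]
    acc = np.eye(3)[np.array([acc_class(v) for v in t.acc])]
    return np.concatenate([t.psfm, t.pssm, ss3, ss8, acc], axis=1)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_QUERY_MAGIC = "# crfthread query profile v1"


def write_query(path, q: QueryRecord) -> None:
    """Whitespace-delimited text profile: header, sequence, one row of
    54 numbers (psfm, pssm, ss3, ss8, acc) per position."""
    rows = query_seq_features(q)
    with open(path, "w") as fh:
        fh.write(f"{_QUERY_MAGIC}\n")
        fh.write(f"name {q.name}\n")
        fh.write(f"length {len(q)}\n")
        fh.write(f"seq {q.sequence}\n")
        for k in range(len(q)):
            vals = " ".join(repr(float(v)) for v in rows[k])
            fh.write(f"{q.sequence[k]} {vals}\n")


def read_query(path) -> QueryRecord:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _QUERY_MAGIC:
        raise ParseError(f"{path}: not a crfthread query profile")
    name = lines[1].split(None, 1)[1].strip()
    length = int(lines[2].split()[1])
    seq = lines[3].split()[1]
    if len(seq) != length:
        raise ParseError(f"{path}: sequence length != declared length")
    body = lines[4 : 4 + length]
    if len(body) != length:
        raise ParseError(f"{path}: expected {length} data rows")
    rows = np.zeros((length, 54))
    for k, ln in enumerate(body):
        parts = ln.split()
        if parts[0] != seq[k]:
            raise ParseError(f"{path}: row {k} residue mismatch")
        if len(parts) != 55:
            raise ParseError(f"{path}: row {k} must carry 54 values")
        rows[k] = [float(v) for v in parts[1:]]
    return QueryRecord(
        sequence=seq,
        psfm=rows[:, :20],
        pssm=rows[:, 20:40],
        ss3=rows[:, 40:43],
        ss8=rows[:, 43:51],
        acc=rows[:, 51:54],
        name=name,
    )


def write_template(pdb_path, meta_path, t: TemplateRecord) -> None:
    """Write ATOM records (CB; CA for glycine) plus a sidecar meta file with
    sequence, secondary-structure label strings and accessibility values."""
    with open(pdb_path, "w") as fh:
        for k, c in enumerate(t.sequence):
            atom = "CA" if c == "G" else "CB"
            res = seq3(c).upper() if c != "X" else "UNK"
            x, y, z = t.coords_cb[k]
            fh.write(
                f"ATOM  {k + 1:5d}  {atom:<3s}{res:>4s} A{k + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")
    with open(meta_path, "w") as fh:
        fh.write(f"name {t.name}\n")
        fh.write(f"seq {t.sequence}\n")
        fh.write("ss3 " + "".join(SS3_CLASSES[c] for c in t.ss3) + "\n")
        fh.write("ss8 " + "".join(SS8_CLASSES[c] for c in t.ss8) + "\n")
        fh.write("acc " + " ".join(repr(float(v)) for v in t.acc) + "\n")


def read_template(pdb_path, meta_path) -> TemplateRecord:
    """Read template coordinates (first model, single chain) and metadata;
    the distance matrix is recomputed from the coordinates."""
    meta = {}
    for ln in Path(meta_path).read_text().splitlines():
        if ln.strip():
            key, val = ln.split(None, 1)
            meta[key] = val.strip()
    seq = meta["seq"]
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("t", str(pdb_path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if len(chains) != 1:
        raise ParseError(f"{pdb_path}: expected a single chain")
    coords = []
    for res in chains[0].get_residues():
        atoms = {a.get_name(): a for a in res.get_atoms()}
        atom = atoms.get("CB", atoms.get("CA"))
        if atom is None:
            raise ParseError(f"{pdb_path}: residue {res.id} lacks CB/CA")
        coords.append(atom.get_coord())
    if len(coords) != len(seq):
        raise ParseError(f"{pdb_path}: {len(coords)} residues but sequence "
                         f"length {len(seq)}")
    ss3 = [SS3_CLASSES.index(c) for c in meta["ss3"]]
    ss8 = [SS8_CLASSES.index(c) for c in meta["ss8"]]
    acc = [float(v) for v in meta["acc"].split()]
    return TemplateRecord(
        sequence=seq,
        coords_cb=np.asarray(coords, dtype=np.float64),
        ss3=ss3,
        ss8=ss8,
        acc=acc,
        name=meta.get("name", "template"),
    )


def save_distance_distribution(path, dd) -> None:
    from .distance import DistanceDistribution  # local import, no cycle at load

    p = dd.p if isinstance(dd, DistanceDistribution) else np.asarray(dd)
    with h5py.File(path, "w") as fh:
        # track_times=False keeps the file byte-reproducible
        fh.create_dataset("dist_pred", data=p, track_times=False)


def load_distance_distribution(path):
    from .distance import DistanceDistribution

    with h5py.File(path, "r") as fh:
        return DistanceDistribution(fh["dist_pred"][...])
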