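"""Per-frame residue contact maps and their image encoding for deep learning.

Two residues are in contact when any pair of their heavy atoms is within
the cutoff (default 4.5 Å, inclusive). Receptor-internal pairs closer than
``min_seq_sep`` in sequence are excluded to suppress trivially permanent
backbone-neighbor contacts; pairs involving a ligand or modulator entity
are exempt from the sequence-separation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ROLE_RECEPTOR
from .errors import ConfigurationError, ValidationError
from .trajio import MolecularSystem, TrajectoryEnsemble

__all__ = [
    "ContactMap",
    "ContactImageSet",
    "compute_contact_map",
    "compute_contact_maps",
    "map_to_image",
    "build_dataset",
    "write_contact_map",
    "read_contact_map",
]


@dataclass
class ContactMap:
    """Symmetric binary residue-contact matrix with zero diagonal."""

    matrix: np.ndarray           # (n_res, n_res) uint8
    cutoff: float
    min_seq_sep: int
    source: str = "frame"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("contact matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValidationError("contact matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("contact matrix diagonal must be zero")
        self.matrix = m.astype(np.uint8)

    @property
    def n_res(self) -> int:
        return self.matrix.shape[0]

    def contact_pairs(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.matrix, k=1))
        return list(zip(ii.tolist(), jj.tolist()))


def _min_distance_matrix(coords: np.ndarray, blocks: list[np.ndarray]) -> np.ndarray:
    """Residue-by-residue minimum heavy-atom distance for one frame."""
    heavy = np.concatenate(blocks)
    starts = np.cumsum([0] + [len(b) for b in blocks])[:-1]
    pts = coords[heavy]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    # reduce atom-pair distances to residue blocks (atoms grouped per residue)
    d = np.minimum.reduceat(d, starts, axis=0)
    d = np.minimum.reduceat(d, starts, axis=1)
    return d


def _seq_sep_mask(system: MolecularSystem, min_seq_sep: int) -> np.ndarray:
    """True where a pair is eligible to be a contact."""
    n = system.n_residues
    roles = np.asarray([r.role for r in system.residues])
    idx = np.arange(n)
    close = np.abs(idx[:, None] - idx[None, :]) < min_seq_sep
    both_receptor = (roles[:, None] == ROLE_RECEPTOR) & (roles[None, :] == ROLE_RECEPTOR)
    mask = ~(close & both_receptor)
    np.fill_diagonal(mask, False)
    return mask


def compute_contact_map(frame: np.ndarray, system: MolecularSystem,
                        cutoff: float = 4.5, min_seq_sep: int = 3,
                        source: str = "frame") -> ContactMap:
    """Contact map of a single frame (coordinates in Å).

    Entry (i, j) = 1 iff the minimum heavy-atom distance between residues
    i and j is <= cutoff (inclusive boundary) and the pair passes the
    sequence-separation rule.
    """
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (system.n_atoms, 3):
        raise ValidationError("frame does not belong to this system")
    blocks = system.heavy_atom_blocks()
    for r, b in zip(system.residues, blocks):
        if len(b) == 0:
            raise ValidationError(f"residue {r.index} ({r.name}) has no heavy atoms")
    d = _min_distance_matrix(frame, blocks)
    mat = ((d <= cutoff) & _seq_sep_mask(system, min_seq_sep)).astype(np.uint8)
    return ContactMap(matrix=mat, cutoff=cutoff, min_seq_sep=min_seq_sep, source=source)


def compute_contact_maps(frames: np.ndarray, system: MolecularSystem,
                         cutoff: float = 4.5, min_seq_sep: int = 3,
                         chunk: int = 400) -> np.ndarray:
    """Vectorized contact matrices for a frame stack: (n_frames, n_res, n_res)."""
    blocks = system.heavy_atom_blocks()
    for r, b in zip(system.residues, blocks):
        if len(b) == 0:
            raise ValidationError(f"residue {r.index} ({r.name}) has no heavy atoms")
    heavy = np.concatenate(blocks)
    starts = np.cumsum([0] + [len(b) for b in blocks])[:-1]
    eligible = _seq_sep_mask(system, min_seq_sep)
    out = np.empty((len(frames), system.n_residues, system.n_residues), dtype=np.uint8)
    for f0 in range(0, len(frames), chunk):
        pts = frames[f0:f0 + chunk][:, heavy]
        d = np.linalg.norm(pts[:, :, None, :] - pts[:, None, :, :], axis=-1)
        d = np.minimum.reduceat(d, starts, axis=1)
        d = np.minimum.reduceat(d, starts, axis=2)
        out[f0:f0 + chunk] = (d <= cutoff) & eligible[None]
    return out


def map_to_image(cmap: ContactMap, pad_to: int | None = None) -> np.ndarray:
    """Single-channel float image: contacts at max intensity (1.0), zero-padded
    bottom/right to ``pad_to`` x ``pad_to``."""
    n = cmap.n_res
    pad_to = n if pad_to is None else pad_to
    if pad_to < n:
        raise ConfigurationError(f"pad_to={pad_to} smaller than n_res={n}")
    img = np.zeros((pad_to, pad_to), dtype=np.float32)
    img[:n, :n] = cmap.matrix
    return img


@dataclass
class ContactImageSet:
    """Contact-map images with class labels and a train/val split."""

    images: np.ndarray            # (n, H, W) float32
    labels: np.ndarray            # (n,) int, index into class_names
    class_names: list[str]
    split: np.ndarray             # (n,) "train" / "val"
    seed: int
    n_res: int                    # data occupies the top-left n_res x n_res block
    train_frac: float = 0.8
    frame_refs: list[tuple] = field(default_factory=list)   # (member_idx, frame_idx)

    @property
    def train_indices(self) -> np.ndarray:
        return np.nonzero(self.split == "train")[0]

    @property
    def val_indices(self) -> np.ndarray:
        return np.nonzero(self.split == "val")[0]


def build_dataset(ensembles: list[TrajectoryEnsemble], train_frac: float = 0.8,
                  seed: int = 0, cutoff: float = 4.5, min_seq_sep: int = 3,
                  pad_to: int | None = None, stride: int = 1) -> ContactImageSet:
    """Compute contact-map images for every (strided) frame and split per
    class at ``train_frac`` with a seeded shuffle."""
    if not ensembles:
        raise ValidationError("no ensembles given")
    conditions = sorted({e.condition for e in ensembles})
    if len(conditions) < 2:
        raise ValidationError("need at least 2 condition classes for a dataset")
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError("train_frac must be in (0, 1): both splits must be non-empty")
    n_res_max = max(e.source_system.n_residues for e in ensembles)
    pad_to = n_res_max if pad_to is None else pad_to
    if pad_to < n_res_max:
        raise ConfigurationError("pad_to smaller than the largest system")

    images, labels, refs = [], [], []
    for mi, ens in enumerate(ensembles):
        frames = ens.frames[::stride]
        mats = compute_contact_maps(frames, ens.source_system, cutoff, min_seq_sep)
        n = ens.source_system.n_residues
        block = np.zeros((len(mats), pad_to, pad_to), dtype=np.float32)
        block[:, :n, :n] = mats
        images.append(block)
        labels.extend([conditions.index(ens.condition)] * len(mats))
        refs.extend((mi, fi * stride) for fi in range(len(mats)))
    images = np.concatenate(images)
    labels = np.asarray(labels)

    split = np.empty(len(labels), dtype=object)
    rng = np.random.default_rng(seed)
    for ci in range(len(conditions)):
        idx = np.nonzero(labels == ci)[0]
        if len(idx) < 5:
            warnings.warn(f"class {conditions[ci]!r} has only {len(idx)} images")
        perm = rng.permutation(len(idx))
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)   # both splits non-empty
        split[idx[perm[:n_train]]] = "train"
        split[idx[perm[n_train:]]] = "val"
    return ContactImageSet(images=images, labels=labels, class_names=conditions,
                           split=split.astype(str), seed=seed, n_res=n_res_max,
                           train_frac=train_frac, frame_refs=refs)


def write_image_png(image: np.ndarray, path) -> None:
    """Save a [0, 1] single-channel image as an 8-bit grayscale PNG."""
    from PIL import Image
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)


# --------------------------------------------------------------------------
# persistence (sparse coordinate text)


def write_contact_map(cmap: ContactMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_res {cmap.n_res} cutoff_A {cmap.cutoff} "
                 f"min_seq_sep {cmap.min_seq_sep} source {cmap.source}\n")
        for i, j in cmap.contact_pairs():
            fh.write(f"{i} {j}\n")


def read_contact_map(path) -> ContactMap:
    n_res, cutoff, seq_sep, source = None, 4.5, 3, "frame"
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                vals = dict(zip(parts[::2], parts[1::2]))
                n_res = int(vals.get("n_res", 0)) or n_res
                cutoff = float(vals.get("cutoff_A", cutoff))
                seq_sep = int(vals.get("min_seq_sep", seq_sep))
                source = vals.get("source", source)
                continue
            i, j = map(int, line.split())
            pairs.append((i, j))
    if n_res is None:
        raise ValidationError("contact-map file lacks n_res header")
    mat = np.zeros((n_res, n_res), dtype=np.uint8)
    for i, j in pairs:
        mat[i, j] = mat[j, i] = 1
    return ContactMap(matrix=mat, cutoff=cutoff, min_seq_sep=seq_sep, source=source)
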