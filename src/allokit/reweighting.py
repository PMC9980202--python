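"""Energetic reweighting of boosted ensembles to free-energy surfaces.

A boosted (enhanced-sampling) run samples exp(-β[V+ΔV]); the unbiased
probability of a reaction-coordinate bin j is recovered from the biased
counts n_j and the bin-local boost moments via

    p_j  ∝  n_j * <exp(βΔV)>_j
    ln <exp(βΔV)>_j  ≈  β C1_j + β² C2_j / 2        (cumulant2)

with C1 the bin mean and C2 the bin variance of ΔV. The second-order
cumulant ("Gaussian approximation") is exact when the bin-local boost is
Gaussian, which is the operating regime the anharmonicity diagnostic
checks. PMF_j = -kT ln p_j, min-shifted to zero over valid bins; bins with
fewer than ``cutoff`` frames are masked invalid and carry no PMF value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._geom import superpose
from .constants import KB, ROLE_RECEPTOR
from .errors import ConfigurationError, ValidationError
from .trajio import BoostSeries, MolecularSystem, TrajectoryEnsemble

__all__ = [
    "CalphaDistance",
    "SegmentRmsd",
    "LigandRmsd",
    "FreeEnergySurface",
    "StateSet",
    "evaluate_rc",
    "reweight",
    "anharmonicity",
    "count_states",
    "write_surface",
    "read_surface",
]


# --------------------------------------------------------------------------
# reaction coordinates (all in Å)


@dataclass(frozen=True)
class CalphaDistance:
    """Cα-Cα distance between two residues."""
    res_i: int
    res_j: int


@dataclass(frozen=True)
class SegmentRmsd:
    """Cα RMSD of a residue range vs a reference structure after
    superposing the alignment selection (receptor Cα by default)."""
    res_start: int
    res_stop: int                  # inclusive
    reference: np.ndarray          # (n_atoms, 3) full-system reference coords
    alignment: np.ndarray | None = None   # atom indices; default receptor Cα


@dataclass(frozen=True)
class LigandRmsd:
    """Heavy-atom RMSD of a ligand/modulator entity vs a reference after
    receptor-Cα superposition."""
    role: str
    reference: np.ndarray


def _calpha_of(system: MolecularSystem, residue: int) -> int:
    for i, atom in enumerate(system.atoms):
        if atom.residue_index == residue and atom.is_calpha:
            return i
    raise ValidationError(f"residue {residue} has no Cα atom")


def evaluate_rc(trajectory: TrajectoryEnsemble, rc) -> np.ndarray:
    """Per-frame reaction-coordinate values in Å."""
    system = trajectory.source_system
    frames = trajectory.frames
    if isinstance(rc, CalphaDistance):
        ai = _calpha_of(system, rc.res_i)
        aj = _calpha_of(system, rc.res_j)
        return np.linalg.norm(frames[:, ai] - frames[:, aj], axis=1)
    if isinstance(rc, SegmentRmsd):
        align = rc.alignment if rc.alignment is not None else system.calpha_indices(ROLE_RECEPTOR)
        seg = np.asarray([_calpha_of(system, r)
                          for r in range(rc.res_start, rc.res_stop + 1)], dtype=int)
        ref = np.asarray(rc.reference, dtype=float)
        out = np.empty(len(frames))
        for f, frame in enumerate(frames):
            moved = superpose(frame, ref, mobile_fit=frame[align], target_fit=ref[align])
            out[f] = np.sqrt(np.mean(np.sum((moved[seg] - ref[seg]) ** 2, axis=1)))
        return out
    if isinstance(rc, LigandRmsd):
        align = system.calpha_indices(ROLE_RECEPTOR)
        heavy = np.asarray([i for i, a in enumerate(system.atoms)
                            if a.is_heavy and system.residues[a.residue_index].role == rc.role],
                           dtype=int)
        if len(heavy) == 0:
            raise ConfigurationError(f"no heavy atoms with role {rc.role!r}")
        ref = np.asarray(rc.reference, dtype=float)
        out = np.empty(len(frames))
        for f, frame in enumerate(frames):
            moved = superpose(frame, ref, mobile_fit=frame[align], target_fit=ref[align])
            out[f] = np.sqrt(np.mean(np.sum((moved[heavy] - ref[heavy]) ** 2, axis=1)))
        return out
    raise ConfigurationError(f"unknown reaction coordinate type {type(rc).__name__}")


# --------------------------------------------------------------------------
# reweighting


@dataclass
class FreeEnergySurface:
    """Binned 1D/2D PMF (kcal/mol) with per-bin counts and validity mask."""

    edges: list[np.ndarray]        # per-dimension bin edges (Å)
    pmf: np.ndarray                # NaN on invalid bins
    counts: np.ndarray
    valid: np.ndarray
    bin_size: float
    cutoff: int
    method: str
    temperature: float

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def bin_centers(self, dim: int = 0) -> np.ndarray:
        e = self.edges[dim]
        return 0.5 * (e[:-1] + e[1:])


_METHODS = ("cumulant2", "exponential", "maclaurin", "unweighted")


def _make_edges(values: np.ndarray, bin_size: float) -> np.ndarray:
    lo = math.floor(values.min() / bin_size) * bin_size
    n = max(1, math.ceil((values.max() - lo) / bin_size + 1e-9))
    return lo + bin_size * np.arange(n + 1)


def reweight(rc_values, boost: BoostSeries, bin_size: float = 1.0,
             cutoff: int = 100, method: str = "cumulant2",
             maclaurin_k: int = 10) -> FreeEnergySurface:
    """Reweight boosted samples on a 1D or 2D reaction-coordinate grid.

    rc_values: one array (1D PMF) or a sequence of two arrays (2D PMF),
    each with one value per frame, matched to ``boost``.
    """
    if method not in _METHODS:
        raise ConfigurationError(f"method must be one of {_METHODS}")
    series = [np.asarray(v, dtype=float) for v in
              (rc_values if isinstance(rc_values, (list, tuple)) else [rc_values])]
    if len(series) not in (1, 2):
        raise ConfigurationError("reweight supports 1 or 2 reaction coordinates")
    n = len(series[0])
    if any(len(s) != n for s in series) or len(boost) != n:
        raise ValidationError("reaction-coordinate and boost series lengths differ")
    if n == 0:
        raise ValidationError("empty input")

    dv = boost.delta_v_total
    beta = 1.0 / (KB * boost.temperature)
    edges = [_make_edges(s, bin_size) for s in series]
    shape = tuple(len(e) - 1 for e in edges)
    # flat bin index per frame (top edge inclusive, as histogram conventions)
    flat = np.zeros(n, dtype=int)
    for dim, (s, e) in enumerate(zip(series, edges)):
        idx = np.clip(np.searchsorted(e, s, side="right") - 1, 0, shape[dim] - 1)
        flat = flat * shape[dim] + idx
    nbins = int(np.prod(shape))
    counts = np.bincount(flat, minlength=nbins).astype(int)
    valid = counts >= cutoff
    if not valid.any():
        raise ValidationError(
            "no bin reaches the frame cutoff; increase bin_size or lower cutoff")

    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "unweighted":
            log_p = np.where(counts > 0, np.log(counts.astype(float)), -np.inf)
        elif method == "exponential":
            sums = np.bincount(flat, weights=np.exp(beta * dv), minlength=nbins)
            log_p = np.where(sums > 0, np.log(sums), -np.inf)
        elif method == "cumulant2":
            c1 = np.zeros(nbins)
            np.add.at(c1, flat, dv)
            c1 = np.where(counts > 0, c1 / np.maximum(counts, 1), 0.0)
            dev2 = (dv - c1[flat]) ** 2
            c2 = np.zeros(nbins)
            np.add.at(c2, flat, dev2)
            c2 = np.where(counts > 0, c2 / np.maximum(counts, 1), 0.0)
            log_p = np.where(counts > 0,
                             np.log(counts.astype(float)) + beta * c1 + 0.5 * beta ** 2 * c2,
                             -np.inf)
        else:  # maclaurin
            log_p = np.full(nbins, -np.inf)
            factor = np.zeros(nbins)
            for k in range(maclaurin_k + 1):
                mk = np.bincount(flat, weights=dv ** k if k else np.ones(n),
                                 minlength=nbins)
                mk = np.where(counts > 0, mk / np.maximum(counts, 1), 0.0)
                factor += beta ** k / math.factorial(k) * mk
            pos = (counts > 0) & (factor > 0)
            log_p[pos] = np.log(counts[pos].astype(float)) + np.log(factor[pos])

    pmf = np.full(nbins, np.nan)
    pmf[valid] = -KB * boost.temperature * log_p[valid]
    pmf[valid] -= pmf[valid].min()
    return FreeEnergySurface(edges=edges, pmf=pmf.reshape(shape),
                             counts=counts.reshape(shape), valid=valid.reshape(shape),
                             bin_size=bin_size, cutoff=cutoff, method=method,
                             temperature=boost.temperature)


# --------------------------------------------------------------------------
# diagnostics


def anharmonicity(delta_v: np.ndarray, n_bins: int = 100) -> float:
    """Entropy deficit γ (nats) of ΔV relative to a matched-variance Gaussian.

    γ = S_gauss - S_emp with S_gauss = ½ ln(2πe σ̂²) and S_emp the
    histogram estimate of the differential entropy. Near 0 means the boost
    is near-Gaussian and second-order cumulant reweighting is adequate.
    """
    dv = np.asarray(delta_v, dtype=float)
    if len(dv) < 100:
        raise ValidationError("anharmonicity needs >= 100 samples")
    sigma = dv.std()
    if sigma == 0:
        raise ValidationError("anharmonicity undefined for zero-variance input")
    hist, edges = np.histogram(dv, bins=n_bins)
    width = edges[1] - edges[0]
    p = hist / hist.sum()
    nz = p > 0
    s_emp = -np.sum(p[nz] * np.log(p[nz] / width))
    s_gauss = 0.5 * math.log(2.0 * math.pi * math.e * sigma ** 2)
    return float(s_gauss - s_emp)


# --------------------------------------------------------------------------
# state counting


@dataclass
class StateSet:
    """Low-energy conformational states: local PMF minima below threshold."""

    states: list[tuple[tuple[float, ...], float]]   # (bin-center coords, PMF)
    threshold: float

    def __len__(self) -> int:
        return len(self.states)


def count_states(surface: FreeEnergySurface, threshold: float = 1.0) -> StateSet:
    """Local minima of the valid-bin PMF with PMF <= global min + threshold.

    Neighborhoods: 2 neighbors in 1D, 8 in 2D; invalid bins do not count
    as neighbors. Plateaus of equal PMF collapse to the lowest-index bin.
    """
    pmf = surface.pmf
    valid = surface.valid
    shape = pmf.shape
    if surface.ndim == 1:
        offsets = [(-1,), (1,)]
        idx_iter = [(i,) for i in range(shape[0])]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                   if (di, dj) != (0, 0)]
        idx_iter = [(i, j) for i in range(shape[0]) for j in range(shape[1])]

    states = []
    for idx in idx_iter:
        if not valid[idx]:
            continue
        val = pmf[idx]
        if val > threshold:
            continue
        is_min = True
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(not 0 <= c < s for c, s in zip(nb, shape)):
                continue
            if not valid[nb]:
                continue
            if pmf[nb] < val:
                is_min = False
                break
            if pmf[nb] == val and nb < idx:
                is_min = False    # plateau: keep lowest-index bin only
                break
        if is_min:
            coords = tuple(float(surface.bin_centers(d)[idx[d]])
                           for d in range(surface.ndim))
            states.append((coords, float(val)))
    return StateSet(states=states, threshold=threshold)


# --------------------------------------------------------------------------
# persistence (plain-text grid table)


def write_surface(surface: FreeEnergySurface, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ndim {surface.ndim} bin_size_A {surface.bin_size} "
                 f"cutoff_frames {surface.cutoff} method {surface.method} "
                 f"temperature_K {surface.temperature}\n")
        for d in range(surface.ndim):
            fh.write("# edges_dim%d %s\n" % (
                d, " ".join(f"{e:.6f}" for e in surface.edges[d])))
        if surface.ndim == 1:
            fh.write("# columns: bin_center_A pmf_kcal_per_mol count valid\n")
            centers = surface.bin_centers(0)
            for c, p, n, v in zip(centers, surface.pmf, surface.counts, surface.valid):
                pm = f"{p:.6f}" if v else "nan"
                fh.write(f"{c:.6f} {pm} {int(n)} {int(v)}\n")
        else:
            fh.write("# columns: bin_center1_A bin_center2_A pmf_kcal_per_mol count valid\n")
            c1 = surface.bin_centers(0)
            c2 = surface.bin_centers(1)
            for i in range(len(c1)):
                for j in range(len(c2)):
                    v = surface.valid[i, j]
                    pm = f"{surface.pmf[i, j]:.6f}" if v else "nan"
                    fh.write(f"{c1[i]:.6f} {c2[j]:.6f} {pm} "
                             f"{int(surface.counts[i, j])} {int(v)}\n")


def read_surface(path) -> FreeEnergySurface:
    meta, edges, rows = {}, [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# edges_dim"):
                parts = line.split()
                edges.append(np.asarray([float(x) for x in parts[2:]]))
            elif line.startswith("# ndim"):
                parts = line[1:].split()
                meta = dict(zip(parts[::2], parts[1::2]))
            elif not line.startswith("#"):
                rows.append(line.split())
    shape = tuple(len(e) - 1 for e in edges)
    pmf = np.full(shape, np.nan)
    counts = np.zeros(shape, dtype=int)
    valid = np.zeros(shape, dtype=bool)
    flat_idx = 0
    for row in rows:
        idx = np.unravel_index(flat_idx, shape)
        pmf[idx] = float(row[-3]) if row[-3] != "nan" else np.nan
        counts[idx] = int(row[-2])
        valid[idx] = bool(int(row[-1]))
        flat_idx += 1
    return FreeEnergySurface(edges=edges, pmf=pmf, counts=counts, valid=valid,
                             bin_size=float(meta["bin_size_A"]),
                             cutoff=int(meta["cutoff_frames"]),
                             method=meta["method"],
                             temperature=float(meta["temperature_K"]))
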