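"""Per-residue flexibility: RMSF, ΔRMSF with the replicate-SD significance
rule, and RMSD time courses.

RMSF is computed after iterative least-squares superposition of all frames
onto the ensemble-average structure (receptor Cα alignment by default),
with the average refined until convergence. Per-replica RMSF profiles are
averaged — the profile of the averaged replicas, not of pooled frames.

ΔRMSF = RMSF(modulator-bound) - RMSF(modulator-free), differenced per
replica; a residue's flexibility change is significant iff the absolute
mean over replicas is at least as large as the replicate SD. The same
operation compares a non-cognate receptor against the cognate one when
given an explicit residue correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geom import superpose
from .constants import ROLE_RECEPTOR
from .errors import ConfigurationError, ValidationError
from .trajio import MolecularSystem, TrajectoryEnsemble

__all__ = [
    "FlexProfile",
    "RmsdSeries",
    "compute_rmsf",
    "delta_rmsf",
    "rmsd_timecourse",
]


@dataclass
class FlexProfile:
    """Per-residue ΔRMSF statistics across replicas."""

    rmsf_bound: np.ndarray       # (n_replicas, n_res)
    rmsf_free: np.ndarray        # (n_replicas, n_res)
    delta: np.ndarray            # (n_replicas, n_res)
    mean_delta: np.ndarray       # (n_res,)
    sd_delta: np.ndarray         # (n_res,)
    significant: np.ndarray      # (n_res,) bool
    pairing: str = "replica"

    @property
    def n_residues(self) -> int:
        return len(self.mean_delta)

    def to_frame(self) -> pd.DataFrame:
        n_rep = self.delta.shape[0]
        data = {"residue": np.arange(self.n_residues)}
        for k in range(n_rep):
            data[f"rmsf_bound_rep{k}"] = self.rmsf_bound[k]
            data[f"rmsf_free_rep{k}"] = self.rmsf_free[k]
            data[f"delta_rep{k}"] = self.delta[k]
        data["mean_delta"] = self.mean_delta
        data["sd_delta"] = self.sd_delta
        data["significant"] = self.significant
        return pd.DataFrame(data)


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) of a selection vs a reference structure."""

    times: np.ndarray            # ns
    values: np.ndarray           # Å
    selection: str
    alignment: str


def _default_alignment(system: MolecularSystem) -> np.ndarray:
    align = system.calpha_indices(ROLE_RECEPTOR)
    if len(align) == 0:
        raise ConfigurationError("no receptor Cα atoms for alignment")
    return align


def _residue_atom_groups(system: MolecularSystem) -> list[np.ndarray]:
    """Representative atoms per residue: Cα for receptor, heavy for others."""
    groups = []
    for res in system.residues:
        if res.role == ROLE_RECEPTOR:
            idx = [i for i, a in enumerate(system.atoms)
                   if a.residue_index == res.index and a.is_calpha]
            if not idx:   # receptor residue without Cα: fall back to heavy atoms
                idx = [i for i, a in enumerate(system.atoms)
                       if a.residue_index == res.index and a.is_heavy]
        else:
            idx = [i for i, a in enumerate(system.atoms)
                   if a.residue_index == res.index and a.is_heavy]
        if not idx:
            raise ValidationError(f"residue {res.index} has no usable atoms for RMSF")
        groups.append(np.asarray(idx, dtype=int))
    return groups


def _iterative_align(frames: np.ndarray, align: np.ndarray,
                     tol: float, max_iter: int) -> np.ndarray:
    """Superpose all frames onto the iteratively refined average structure."""
    ref = frames[0]
    moved = frames
    for _ in range(max_iter):
        moved = np.stack([superpose(f, ref, mobile_fit=f[align], target_fit=ref[align])
                          for f in moved])
        new_ref = moved.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_ref[align] - ref[align]) ** 2, axis=1)))
        ref = new_ref
        if shift < tol:
            break
    return moved


def compute_rmsf(trajectory: TrajectoryEnsemble,
                 alignment_selection: np.ndarray | None = None,
                 tol: float = 1e-4, max_iter: int = 10,
                 core_frac: float | None = 0.5) -> np.ndarray:
    """Per-residue RMSF (Å) about the iteratively refined average structure.

    Residue RMSF is the mean over its representative atoms of the per-atom
    root-mean-square deviation from the time-average position.

    With ``core_frac`` set (default 0.5), the superposition is refined on
    the stable core: after a first pass on the full alignment selection,
    the least-mobile fraction of those atoms re-anchors the fit. This
    keeps a few large-amplitude residues from dragging the frame of
    reference and bleeding apparent flexibility into every other residue.
    ``core_frac=None`` aligns on the full selection only.
    """
    system = trajectory.source_system
    frames = trajectory.frames
    if len(frames) < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    align = (np.asarray(alignment_selection, dtype=int)
             if alignment_selection is not None else _default_alignment(system))
    if len(align) == 0:
        raise ConfigurationError("empty alignment selection")

    moved = _iterative_align(frames, align, tol, max_iter)
    if core_frac is not None and len(align) >= 6:
        mean_pos = moved.mean(axis=0)
        fluct = np.sqrt(np.mean(np.sum((moved[:, align] - mean_pos[align]) ** 2,
                                       axis=2), axis=0))
        n_core = max(3, int(round(core_frac * len(align))))
        core = align[np.argsort(fluct, kind="stable")[:n_core]]
        moved = _iterative_align(frames, np.sort(core), tol, max_iter)

    mean_pos = moved.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((moved - mean_pos) ** 2, axis=2), axis=0))
    return np.asarray([atom_rmsf[g].mean() for g in _residue_atom_groups(system)])


def delta_rmsf(bound_profiles: list[np.ndarray], free_profiles: list[np.ndarray],
               pairing: str = "replica",
               residue_map: np.ndarray | None = None) -> FlexProfile:
    """ΔRMSF = bound - free with the |mean| >= SD significance rule.

    pairing="replica" (default) differences replica k against replica k and
    takes mean/SD of the per-replica differences — the only pairing that
    yields replicate ΔRMSF values for the stated rule. pairing="mean"
    differences the replica means, with the SD propagated in quadrature.

    residue_map maps bound-side residue indices to free-side indices for
    cross-receptor (cognate vs non-cognate) comparisons; identity when
    None.
    """
    if len(bound_profiles) != len(free_profiles):
        raise ValidationError("replica count mismatch between bound and free")
    bound = np.vstack(bound_profiles)
    free = np.vstack(free_profiles)
    if residue_map is not None:
        residue_map = np.asarray(residue_map, dtype=int)
        free = free[:, residue_map]
    if bound.shape != free.shape:
        raise ValidationError("residue count mismatch; supply residue_map")
    n_rep = bound.shape[0]
    if pairing == "replica":
        delta = bound - free
        mean = delta.mean(axis=0)
        sd = delta.std(axis=0, ddof=1) if n_rep > 1 else np.zeros(delta.shape[1])
    elif pairing == "mean":
        delta = bound - free.mean(axis=0, keepdims=True)
        mean = bound.mean(axis=0) - free.mean(axis=0)
        if n_rep > 1:
            sd = np.sqrt(bound.std(axis=0, ddof=1) ** 2 + free.std(axis=0, ddof=1) ** 2)
        else:
            sd = np.zeros(bound.shape[1])
    else:
        raise ConfigurationError("pairing must be 'replica' or 'mean'")
    # |mean| = SD is significant (the rule states the NOT-significant side
    # strictly); an exactly zero change never is (identical ensembles).
    significant = (np.abs(mean) >= sd) & (np.abs(mean) > 0)
    return FlexProfile(rmsf_bound=bound, rmsf_free=free, delta=bound - free,
                       mean_delta=mean, sd_delta=sd, significant=significant,
                       pairing=pairing)


def rmsd_timecourse(trajectory: TrajectoryEnsemble, reference_frame: np.ndarray,
                    selection: np.ndarray,
                    alignment_selection: np.ndarray | None = None,
                    selection_name: str = "selection") -> RmsdSeries:
    """Per-frame RMSD of ``selection`` vs a reference structure.

    Each frame is superposed onto the reference using the alignment
    selection (receptor Cα by default); the selection RMSD is then taken
    without refitting — the standard ligand-RMSD convention.
    """
    system = trajectory.source_system
    reference_frame = np.asarray(reference_frame, dtype=float)
    if reference_frame.shape != (system.n_atoms, 3):
        raise ValidationError("reference frame does not match the system")
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ConfigurationError("empty selection")
    align = (np.asarray(alignment_selection, dtype=int)
             if alignment_selection is not None else _default_alignment(system))
    values = np.empty(trajectory.n_frames)
    for f, frame in enumerate(trajectory.frames):
        moved = superpose(frame, reference_frame,
                          mobile_fit=frame[align], target_fit=reference_frame[align])
        values[f] = np.sqrt(np.mean(np.sum(
            (moved[selection] - reference_frame[selection]) ** 2, axis=1)))
    return RmsdSeries(times=trajectory.frame_times.copy(), values=values,
                      selection=selection_name, alignment="receptor-CA")
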