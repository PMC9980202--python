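"""Readers/writers for topologies, trajectories and boost-potential logs.

Everything downstream of this module consumes only the in-memory domain
types defined here: :class:`MolecularSystem`, :class:`TrajectoryEnsemble`
and :class:`BoostSeries`.

Unit contract: coordinates are always Å internally, times always ns,
energies kcal/mol. XTC files (nm) are converted on read/write. Residue
and frame indices are 0-based internally; 1-based numbering appears only
in PDB files and report surfaces.

The boost-log dialect is whitespace-separated text, ``#`` comment/header
lines, and one record per saved trajectory frame::

    # frame  dV_total(kcal/mol)  [dV_dihedral(kcal/mol)]
    0  12.5  3.1
    1  14.0  2.9
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import CONDITION_LABELS, ROLE_MODULATOR, ROLE_ORTHOSTERIC, ROLE_RECEPTOR, ROLES
from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "Atom",
    "Residue",
    "MolecularSystem",
    "TrajectoryEnsemble",
    "BoostSeries",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_boost_log",
    "write_boost_log",
]


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Residue:
    index: int                 # 0-based, contiguous
    name: str
    chain_id: str
    role: str = ROLE_RECEPTOR
    pdb_resseq: int | None = None   # author numbering, report surfaces only


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_index: int
    is_heavy: bool
    is_calpha: bool


@dataclass
class MolecularSystem:
    """Residues and atoms with receptor/ligand/modulator roles."""

    residues: list[Residue]
    atoms: list[Atom]

    def __post_init__(self) -> None:
        for i, res in enumerate(self.residues):
            if res.index != i:
                raise ValidationError(
                    f"residue indices must be contiguous from 0; got {res.index} at {i}")
        n_res = len(self.residues)
        for atom in self.atoms:
            if not 0 <= atom.residue_index < n_res:
                raise ValidationError(
                    f"atom {atom.name} references missing residue {atom.residue_index}")
            if atom.is_heavy != (atom.element != "H"):
                raise ValidationError("is_heavy must mirror element != H")
        for res in self.residues:
            if res.role not in ROLES:
                raise ValidationError(f"unknown role {res.role!r}")
        # at most one allosteric-modulator group (contiguous residue block)
        mod = [r.index for r in self.residues if r.role == ROLE_MODULATOR]
        if mod and (max(mod) - min(mod) + 1 != len(mod)):
            raise ValidationError("allosteric_modulator role must form one residue group")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_indices_of_residue(self, residue_index: int, heavy_only: bool = False) -> np.ndarray:
        idx = [i for i, a in enumerate(self.atoms)
               if a.residue_index == residue_index and (a.is_heavy or not heavy_only)]
        return np.asarray(idx, dtype=int)

    def heavy_atom_blocks(self) -> list[np.ndarray]:
        """Per-residue arrays of heavy-atom indices, residue order."""
        blocks: list[list[int]] = [[] for _ in self.residues]
        for i, atom in enumerate(self.atoms):
            if atom.is_heavy:
                blocks[atom.residue_index].append(i)
        return [np.asarray(b, dtype=int) for b in blocks]

    def calpha_indices(self, role: str | None = ROLE_RECEPTOR) -> np.ndarray:
        idx = []
        for i, atom in enumerate(self.atoms):
            if not atom.is_calpha:
                continue
            if role is None or self.residues[atom.residue_index].role == role:
                idx.append(i)
        return np.asarray(idx, dtype=int)

    def residue_indices(self, role: str) -> np.ndarray:
        return np.asarray([r.index for r in self.residues if r.role == role], dtype=int)


@dataclass
class TrajectoryEnsemble:
    """Coordinates of one replica of one condition, Å and ns."""

    frames: np.ndarray            # (n_frames, n_atoms, 3)
    frame_times: np.ndarray       # ns, strictly increasing
    replica_id: int
    condition: str
    source_system: MolecularSystem

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.source_system.n_atoms:
            raise ValidationError(
                f"atom count {self.frames.shape[1]} does not match topology "
                f"({self.source_system.n_atoms})")
        if len(self.frame_times) != len(self.frames):
            raise ValidationError("frame_times length must match frames")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValidationError("frame_times must be strictly increasing")
        if self.condition not in CONDITION_LABELS:
            raise ValidationError(
                f"condition {self.condition!r} not in {CONDITION_LABELS}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class BoostSeries:
    """Per-frame boost potential ΔV (kcal/mol) at a simulation temperature."""

    delta_v_total: np.ndarray
    temperature: float
    delta_v_dihedral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_v_total = np.asarray(self.delta_v_total, dtype=float)
        if self.delta_v_dihedral is not None:
            self.delta_v_dihedral = np.asarray(self.delta_v_dihedral, dtype=float)
            if len(self.delta_v_dihedral) != len(self.delta_v_total):
                raise ValidationError("dihedral boost length mismatch")
        if np.any(self.delta_v_total < 0):
            raise ValidationError("boost potential must be non-negative")
        if self.delta_v_dihedral is not None and np.any(self.delta_v_dihedral < 0):
            raise ValidationError("boost potential must be non-negative")
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive")

    def __len__(self) -> int:
        return len(self.delta_v_total)


def validate_pair(ensemble: TrajectoryEnsemble, boost: BoostSeries) -> None:
    """A boost series must carry exactly one record per saved frame."""
    if len(boost) != ensemble.n_frames:
        raise ValidationError(
            f"boost series length {len(boost)} != {ensemble.n_frames} frames")


# --------------------------------------------------------------------------
# PDB parsing (fixed-column ATOM/HETATM records)

_HETATM_ROLES = {ROLE_ORTHOSTERIC, ROLE_MODULATOR}


def _element_from_fields(line: str, atom_name: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem.capitalize()
    # fall back to the atom-name convention: strip digits, take leading letter(s)
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError("cannot infer element")
    if stripped[:2].upper() in {"CL", "BR", "NA", "MG", "ZN", "FE", "CA"} and len(atom_name.strip()) <= 2:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _iter_lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


def _match_selection(sel: dict, chain: str, resname: str, resseq: int) -> bool:
    if "chains" in sel and chain not in sel["chains"]:
        return False
    if "resnames" in sel and resname not in sel["resnames"]:
        return False
    if "resids" in sel and resseq not in sel["resids"]:
        return False
    return True


def read_topology(pdb_source, role_spec: dict | None = None) -> MolecularSystem:
    """Parse ATOM/HETATM records of a PDB into a :class:`MolecularSystem`.

    role_spec maps a role name to a selection dict with any of the keys
    ``chains`` (chain ids), ``resnames`` (residue names) and ``resids``
    (author 1-based residue numbers). Unassigned residues default to the
    receptor role; HETATM-only residues with no assignment default to
    orthosteric_ligand.
    """
    role_spec = role_spec or {}
    for role in role_spec:
        if role not in ROLES:
            raise ConfigurationError(f"unknown role {role!r} in role_spec")

    residues: list[Residue] = []
    atoms: list[Atom] = []
    res_key_to_index: dict[tuple, int] = {}
    res_is_het: list[bool] = []
    n_lines = 0
    for lineno, raw in enumerate(_iter_lines(pdb_source), start=1):
        n_lines += 1
        record = raw[:6].strip()
        if record == "ENDMDL":
            break  # topology comes from the first model only
        if record not in ("ATOM", "HETATM"):
            continue
        if len(raw.rstrip("\n")) < 54:
            raise ParseError(f"line {lineno}: truncated {record} record")
        try:
            name = raw[12:16].strip()
            resname = raw[17:20].strip() or raw[17:21].strip()
            chain = raw[21].strip() or "A"
            resseq = int(raw[22:26])
            float(raw[30:38]); float(raw[38:46]); float(raw[46:54])
            element = _element_from_fields(raw, name)
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: malformed {record} record ({exc})") from exc
        key = (chain, resseq, resname)
        if key not in res_key_to_index:
            res_key_to_index[key] = len(residues)
            residues.append(Residue(index=len(residues), name=resname,
                                    chain_id=chain, pdb_resseq=resseq))
            res_is_het.append(record == "HETATM")
        ridx = res_key_to_index[key]
        atoms.append(Atom(name=name, element=element, residue_index=ridx,
                          is_heavy=element != "H",
                          is_calpha=(name == "CA" and element == "C")))
    if not atoms:
        raise ParseError(f"line {n_lines}: no ATOM/HETATM records found")

    # role assignment: explicit selections first, then HETATM->ligand default
    matched = {role: 0 for role in role_spec}
    assigned: list[str] = []
    for res, het in zip(residues, res_is_het):
        role = None
        for cand in (ROLE_MODULATOR, ROLE_ORTHOSTERIC, ROLE_RECEPTOR):
            sel = role_spec.get(cand)
            if sel is not None and _match_selection(sel, res.chain_id, res.name, res.pdb_resseq):
                role = cand
                matched[cand] += 1
                break
        if role is None:
            role = ROLE_ORTHOSTERIC if (het and ROLE_ORTHOSTERIC not in role_spec) else ROLE_RECEPTOR
        assigned.append(role)
    for role, sel in role_spec.items():
        if matched[role] == 0:
            raise ConfigurationError(f"role_spec selection for {role!r} matched no residue")
    residues = [Residue(index=r.index, name=r.name, chain_id=r.chain_id,
                        role=role, pdb_resseq=r.pdb_resseq)
                for r, role in zip(residues, assigned)]
    return MolecularSystem(residues=residues, atoms=atoms)


def read_topology_coordinates(pdb_source) -> np.ndarray:
    """Coordinates (Å) of the first model of a PDB, atom order preserved."""
    coords = []
    for lineno, raw in enumerate(_iter_lines(pdb_source), start=1):
        record = raw[:6].strip()
        if record == "ENDMDL":
            break
        if record in ("ATOM", "HETATM"):
            try:
                coords.append((float(raw[30:38]), float(raw[38:46]), float(raw[46:54])))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed coordinates") from exc
    if not coords:
        raise ParseError("no ATOM/HETATM records found")
    return np.asarray(coords)


def _pdb_atom_line(i: int, atom: Atom, res: Residue, xyz: np.ndarray) -> str:
    record = "ATOM  " if res.role == ROLE_RECEPTOR else "HETATM"
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    resseq = res.pdb_resseq if res.pdb_resseq is not None else res.index + 1
    return (f"{record}{i + 1:5d} {name:<4.4s} {res.name:<3.3s} {res.chain_id:1.1s}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2.2s}\n")


def write_topology(system: MolecularSystem, coords: np.ndarray, path,
                   remarks: Sequence[str] = ()) -> None:
    """Write a single-model PDB with element columns and role provenance."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_atoms, 3):
        raise ValidationError("coords shape must be (n_atoms, 3)")
    with open(path, "w") as fh:
        for rem in remarks:
            fh.write(f"REMARK   1 {rem}\n")
        for i, atom in enumerate(system.atoms):
            fh.write(_pdb_atom_line(i, atom, system.residues[atom.residue_index], coords[i]))
        fh.write("END\n")


# --------------------------------------------------------------------------
# trajectories


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(str(path)).suffix.lower().lstrip(".")
    if suffix in ("pdb", "dcd", "xtc"):
        return suffix
    raise ConfigurationError(f"cannot infer trajectory format from {path!r}")


def _read_multimodel_pdb(source, n_atoms: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    current: list[tuple] = []
    saw_model = False
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        record = raw[:6].strip()
        if record == "MODEL":
            saw_model = True
            current = []
        elif record in ("ATOM", "HETATM"):
            try:
                current.append((float(raw[30:38]), float(raw[38:46]), float(raw[46:54])))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed coordinates") from exc
        elif record == "ENDMDL":
            if len(current) != n_atoms:
                raise ValidationError(
                    f"model ending at line {lineno} has {len(current)} atoms, expected {n_atoms}")
            frames.append(np.asarray(current))
            current = []
    if not saw_model:
        if len(current) != n_atoms:
            raise ValidationError(
                f"file has {len(current)} atoms, expected {n_atoms}")
        frames.append(np.asarray(current))
    elif current:
        raise ParseError("truncated final model (missing ENDMDL)")
    if not frames:
        raise ParseError("no coordinate models found")
    return np.stack(frames)


def read_trajectory(system: MolecularSystem, path, format: str | None = None, *,
                    condition: str = "Apo", replica_id: int = 0,
                    dt_ns: float = 0.01) -> TrajectoryEnsemble:
    """Read DCD/XTC/multi-model-PDB coordinates into Å.

    Frame times are synthesized as ``dt_ns * frame_index`` (default 10 ps
    per saved frame) because none of the supported formats reliably stores
    physical times.
    """
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        frames = _read_multimodel_pdb(path, system.n_atoms)
    elif fmt in ("dcd", "xtc"):
        import MDAnalysis as mda
        from MDAnalysis.coordinates.DCD import DCDReader
        from MDAnalysis.coordinates.XTC import XTCReader

        reader_cls = DCDReader if fmt == "dcd" else XTCReader
        try:
            reader = reader_cls(str(path))
        except Exception as exc:  # pragma: no cover - backend specifics
            raise ParseError(f"failed to open {fmt.upper()} file {path}: {exc}") from exc
        with reader:
            if reader.n_atoms != system.n_atoms:
                raise ValidationError(
                    f"{fmt.upper()} file has {reader.n_atoms} atoms, "
                    f"expected {system.n_atoms}")
            # MDAnalysis converts to Å on read for both formats
            frames = np.stack([ts.positions.astype(float).copy() for ts in reader])
    else:
        raise ConfigurationError(f"unsupported trajectory format {fmt!r}")
    times = dt_ns * np.arange(len(frames), dtype=float)
    return TrajectoryEnsemble(frames=frames, frame_times=times,
                              replica_id=replica_id, condition=condition,
                              source_system=system)


def write_trajectory(system: MolecularSystem, frames: np.ndarray, path,
                     format: str | None = None, remarks: Sequence[str] = ()) -> None:
    """Write frames (Å) as multi-model PDB, DCD or XTC."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1:] != (system.n_atoms, 3):
        raise ValidationError("frames shape must be (n_frames, n_atoms, 3)")
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        with open(path, "w") as fh:
            for rem in remarks:
                fh.write(f"REMARK   1 {rem}\n")
            for m, frame in enumerate(frames, start=1):
                fh.write(f"MODEL {m:8d}\n")
                for i, atom in enumerate(system.atoms):
                    fh.write(_pdb_atom_line(i, atom, system.residues[atom.residue_index],
                                            frame[i]))
                fh.write("ENDMDL\n")
            fh.write("END\n")
        return
    if fmt not in ("dcd", "xtc"):
        raise ConfigurationError(f"unsupported trajectory format {fmt!r}")
    import MDAnalysis as mda

    u = mda.Universe.empty(system.n_atoms, trajectory=True)
    # XTC positions are stored as nm * 10^precision; 4 digits -> 1e-4 nm
    # quantization = 1e-3 Å, matching the round-trip contract
    kwargs = {"precision": 4} if fmt == "xtc" else {}
    with mda.Writer(str(path), n_atoms=system.n_atoms, **kwargs) as writer:
        with warnings.catch_warnings():
            # no box: synthetic/fixture data are whole-molecule, unwrapped
            warnings.filterwarnings("ignore", message=".*unitcell.*")
            for frame in frames:
                u.atoms.positions = frame
                writer.write(u.atoms)


# --------------------------------------------------------------------------
# boost logs


def read_boost_log(source, temperature: float) -> BoostSeries:
    """Parse the boost-log dialect (see module docstring)."""
    totals: list[float] = []
    dihedrals: list[float] = []
    last_frame = -1
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: expected 'frame dV_total [dV_dihedral]'")
        try:
            frame = int(parts[0])
            dv = float(parts[1])
            dvd = float(parts[2]) if len(parts) > 2 else None
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field") from exc
        if frame <= last_frame:
            raise ValidationError(
                f"line {lineno}: frame index {frame} not increasing (previous {last_frame})")
        if dv < 0 or (dvd is not None and dvd < 0):
            raise ValidationError(f"line {lineno}: negative boost potential")
        last_frame = frame
        totals.append(dv)
        if dvd is not None:
            dihedrals.append(dvd)
    if not totals:
        warnings.warn("boost log contains no data lines; returning empty series")
    if dihedrals and len(dihedrals) != len(totals):
        raise ParseError("dihedral boost column present only on some lines")
    return BoostSeries(delta_v_total=np.asarray(totals),
                       delta_v_dihedral=np.asarray(dihedrals) if dihedrals else None,
                       temperature=temperature)


def write_boost_log(series: BoostSeries, path, remarks: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for rem in remarks:
            fh.write(f"# {rem}\n")
        if series.delta_v_dihedral is not None:
            fh.write("# frame dV_total(kcal/mol) dV_dihedral(kcal/mol)\n")
            for i, (dv, dvd) in enumerate(zip(series.delta_v_total, series.delta_v_dihedral)):
                fh.write(f"{i} {dv:.6f} {dvd:.6f}\n")
        else:
            fh.write("# frame dV_total(kcal/mol)\n")
            for i, dv in enumerate(series.delta_v_total):
                fh.write(f"{i} {dv:.6f}\n")
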