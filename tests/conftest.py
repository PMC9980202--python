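"""Shared fixtures: synthetic ensembles are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from allokit.ensemble import cluster_conformations, representative_contact_map
from allokit.flexibility import compute_rmsf, delta_rmsf
from allokit.synthetic import SyntheticSpec, generate_ensemble
from allokit.trajio import Atom, MolecularSystem, Residue

TOY_PDB = """\
REMARK   1 three-residue toy with one HETATM ligand
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  HA  ALA A   1       1.800   1.000   0.000  1.00  0.00           H
ATOM      4  N   GLY A   2       2.000   0.000   1.300  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.450   0.000   1.300  1.00  0.00           C
HETATM    6  C1  LIG L   1       6.000   0.000   0.000  1.00  0.00           C
HETATM    7  C2  LIG L   1       7.400   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec()


@pytest.fixture(scope="session")
def default_data(default_spec):
    """(system, members, truth) for the default synthetic study conditions."""
    return generate_ensemble(default_spec)


@pytest.fixture(scope="session")
def members_by_condition(default_spec, default_data):
    _, members, _ = default_data
    free = [m for m in members if m[0].condition == default_spec.free_condition]
    bound = [m for m in members if m[0].condition == default_spec.bound_condition]
    return free, bound


@pytest.fixture(scope="session")
def flex_profile(members_by_condition):
    """ΔRMSF profile (bound - free) for the default synthetic system."""
    free, bound = members_by_condition
    bound_profiles = [compute_rmsf(t) for t, _ in bound]
    free_profiles = [compute_rmsf(t) for t, _ in free]
    return delta_rmsf(bound_profiles, free_profiles)


@pytest.fixture(scope="session")
def bound_reference_map(default_data, members_by_condition):
    """Most-populated-cluster representative contact map, bound condition."""
    system, _, _ = default_data
    _, bound = members_by_condition
    trajs = [t for t, _ in bound]
    res = cluster_conformations(trajs)
    return representative_contact_map(res, trajs, system)


def make_bead_system(n_res: int, atoms_per_res: int = 1,
                     roles: list[str] | None = None) -> MolecularSystem:
    """Small all-carbon test system; first atom of each residue is the Cα."""
    residues, atoms = [], []
    for i in range(n_res):
        role = roles[i] if roles else "receptor"
        residues.append(Residue(index=i, name="ALA" if role == "receptor" else "LIG",
                                chain_id="A", role=role, pdb_resseq=i + 1))
        for a in range(atoms_per_res):
            atoms.append(Atom(name="CA" if a == 0 else f"C{a}", element="C",
                              residue_index=i, is_heavy=True, is_calpha=(a == 0)))
    return MolecularSystem(residues=residues, atoms=atoms)


@pytest.fixture
def bead_system():
    return make_bead_system


@pytest.fixture
def toy_pdb_text():
    return TOY_PDB
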