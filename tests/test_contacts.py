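"""Contact-map definition, image encoding and dataset splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokit.contacts import (ContactMap, build_dataset, compute_contact_map,
                              compute_contact_maps, map_to_image, read_contact_map,
                              write_contact_map)
from allokit.errors import ConfigurationError, ValidationError
from allokit.trajio import Atom, MolecularSystem, Residue, TrajectoryEnsemble
from conftest import make_bead_system


def brute_force_map(frame, system, cutoff, min_seq_sep):
    """Independent oracle: all-pairs atom scan with explicit loops."""
    n = system.n_residues
    out = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ri, rj = system.residues[i], system.residues[j]
            both_receptor = ri.role == "receptor" and rj.role == "receptor"
            if both_receptor and abs(i - j) < min_seq_sep:
                continue
            dmin = min(
                float(np.linalg.norm(frame[a] - frame[b]))
                for a, atom_a in enumerate(system.atoms)
                if atom_a.residue_index == i and atom_a.is_heavy
                for b, atom_b in enumerate(system.atoms)
                if atom_b.residue_index == j and atom_b.is_heavy)
            out[i, j] = dmin <= cutoff
    return out


class TestContactDefinition:
    def test_inclusive_boundary_at_cutoff(self, bead_system):
        system = bead_system(2)
        frame = np.array([[0.0, 0, 0], [4.5, 0, 0]])
        cmap = compute_contact_map(frame, system, cutoff=4.5, min_seq_sep=0)
        assert cmap.matrix[0, 1] == 1

    def test_just_beyond_cutoff(self, bead_system):
        system = bead_system(2)
        frame = np.array([[0.0, 0, 0], [4.6, 0, 0]])
        cmap = compute_contact_map(frame, system, cutoff=4.5, min_seq_sep=0)
        assert cmap.matrix[0, 1] == 0

    @pytest.mark.parametrize("cutoff", [4.5, 6.0])
    @pytest.mark.parametrize("min_seq_sep", [0, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_toys(self, cutoff, min_seq_sep, seed):
        """Randomized 10-residue multi-atom systems against the all-pairs oracle."""
        system = make_bead_system(10, atoms_per_res=3,
                                  roles=["receptor"] * 9 + ["orthosteric_ligand"])
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 12, size=(system.n_atoms, 3))
        got = compute_contact_map(frame, system, cutoff, min_seq_sep).matrix
        assert np.array_equal(got, brute_force_map(frame, system, cutoff, min_seq_sep))
        batch = compute_contact_maps(frame[None], system, cutoff, min_seq_sep)[0]
        assert np.array_equal(batch, got)

    def test_inter_entity_pairs_exempt_from_seq_sep(self):
        system = make_bead_system(3, roles=["receptor", "receptor", "orthosteric_ligand"])
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0], [3.0, 1.0, 0]])
        cmap = compute_contact_map(frame, system, cutoff=4.5, min_seq_sep=3)
        assert cmap.matrix[0, 1] == 0     # receptor pair, |i-j| < 3
        assert cmap.matrix[1, 2] == 1     # ligand pair exempt

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        system = make_bead_system(6)
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 15, size=(6, 3))
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = frame @ q + rng.uniform(-30, 30, size=3)
        a = compute_contact_map(frame, system, 6.0, 0).matrix
        b = compute_contact_map(moved, system, 6.0, 0).matrix
        assert np.array_equal(a, b)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_raising_cutoff_never_removes_contacts(self, seed):
        system = make_bead_system(6)
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 15, size=(6, 3))
        low = compute_contact_map(frame, system, 4.5, 0).matrix
        high = compute_contact_map(frame, system, 7.0, 0).matrix
        assert np.all(high >= low)

    def test_residue_without_heavy_atoms_rejected(self):
        residues = [Residue(index=0, name="ALA", chain_id="A"),
                    Residue(index=1, name="HHH", chain_id="A")]
        atoms = [Atom("CA", "C", 0, True, True), Atom("H", "H", 1, False, False)]
        system = MolecularSystem(residues=residues, atoms=atoms)
        with pytest.raises(ValidationError, match="no heavy atoms"):
            compute_contact_map(np.zeros((2, 3)), system)

    def test_matrix_validation(self):
        bad = np.array([[0, 1], [0, 0]], dtype=np.uint8)
        with pytest.raises(ValidationError, match="symmetric"):
            ContactMap(matrix=bad, cutoff=4.5, min_seq_sep=0)


class TestImageEncoding:
    def _map(self, n, pairs):
        m = np.zeros((n, n), dtype=np.uint8)
        for i, j in pairs:
            m[i, j] = m[j, i] = 1
        return ContactMap(matrix=m, cutoff=4.5, min_seq_sep=0)

    def test_all_zero_map(self):
        img = map_to_image(self._map(4, []))
        assert img.shape == (4, 4) and img.sum() == 0

    def test_pixel_count_is_twice_contact_count(self):
        img = map_to_image(self._map(6, [(0, 3), (1, 4), (2, 5)]))
        assert (img == 1.0).sum() == 6

    def test_padding_keeps_data_top_left(self):
        img = map_to_image(self._map(10, [(0, 9)]), pad_to=12)
        assert img.shape == (12, 12)
        assert img[10:, :].sum() == 0 and img[:, 10:].sum() == 0
        assert img[0, 9] == 1.0

    def test_pad_smaller_than_map_rejected(self):
        with pytest.raises(ConfigurationError):
            map_to_image(self._map(4, []), pad_to=3)


def _tiny_ensembles(n_frames=20, conditions=("Agonist", "AgonistPAM")):
    system = make_bead_system(4)
    rng = np.random.default_rng(0)
    out = []
    for cond in conditions:
        frames = rng.uniform(0, 10, size=(n_frames, 4, 3))
        out.append(TrajectoryEnsemble(frames=frames,
                                      frame_times=0.01 * np.arange(n_frames),
                                      replica_id=0, condition=cond,
                                      source_system=system))
    return out


class TestDatasetSplit:
    def test_eighty_twenty_per_class(self):
        ds = build_dataset(_tiny_ensembles(100), train_frac=0.8, seed=0)
        for ci in range(2):
            mask = ds.labels == ci
            assert (ds.split[mask] == "train").sum() == 80
            assert (ds.split[mask] == "val").sum() == 20

    def test_split_reproducible_from_seed(self):
        a = build_dataset(_tiny_ensembles(50), seed=9)
        b = build_dataset(_tiny_ensembles(50), seed=9)
        assert np.array_equal(a.split, b.split)
        c = build_dataset(_tiny_ensembles(50), seed=10)
        assert not np.array_equal(a.split, c.split)

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            build_dataset(_tiny_ensembles(20), train_frac=1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="2 condition classes"):
            build_dataset(_tiny_ensembles(20, conditions=("Agonist",)))

    def test_small_class_warns(self):
        with pytest.warns(UserWarning, match="only"):
            build_dataset(_tiny_ensembles(4), train_frac=0.5)


def test_png_export_preserves_pixels(tmp_path):
    from PIL import Image
    from allokit.contacts import write_image_png
    img = np.zeros((8, 8), dtype=np.float32)
    img[1, 5] = img[5, 1] = 1.0
    path = tmp_path / "map.png"
    write_image_png(img, path)
    back = np.asarray(Image.open(path)) / 255.0
    assert np.array_equal(back, img)


def test_contact_map_text_round_trip(tmp_path):
    system = make_bead_system(5)
    frame = np.random.default_rng(3).uniform(0, 8, size=(5, 3))
    cmap = compute_contact_map(frame, system, cutoff=6.0, min_seq_sep=0)
    path = tmp_path / "map.txt"
    write_contact_map(cmap, path)
    back = read_contact_map(path)
    assert np.array_equal(back.matrix, cmap.matrix)
    assert back.cutoff == cmap.cutoff
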