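"""Reaction coordinates, energetic reweighting, anharmonicity, state counts."""

import math

import numpy as np
import pytest

from allokit.constants import KB
from allokit.errors import ValidationError
from allokit.reweighting import (CalphaDistance, FreeEnergySurface, LigandRmsd,
                                 SegmentRmsd, anharmonicity, count_states,
                                 evaluate_rc, read_surface, reweight, write_surface)
from allokit.trajio import BoostSeries, TrajectoryEnsemble
from conftest import make_bead_system

T = 310.0
BETA = 1.0 / (KB * T)


def _boost(dv):
    return BoostSeries(delta_v_total=np.asarray(dv, dtype=float), temperature=T)


def _traj(frames, system, condition="Apo"):
    return TrajectoryEnsemble(frames=np.asarray(frames, dtype=float),
                              frame_times=0.01 * np.arange(len(frames)),
                              replica_id=0, condition=condition,
                              source_system=system)


class TestReactionCoordinates:
    def test_calpha_distance_closed_form(self):
        system = make_bead_system(2)
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        vals = evaluate_rc(_traj([frame], system), CalphaDistance(0, 1))
        assert vals[0] == pytest.approx(5.0)

    def test_segment_identical_to_reference_is_zero(self):
        system = make_bead_system(5)
        ref = np.random.default_rng(0).uniform(0, 10, size=(5, 3))
        rc = SegmentRmsd(1, 3, reference=ref)
        vals = evaluate_rc(_traj([ref], system), rc)
        assert vals[0] == pytest.approx(0.0, abs=1e-9)

    def test_segment_rmsd_matches_kabsch_oracle(self):
        """Rotated+perturbed frame against an independent superposition."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd
        system = make_bead_system(5)
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 10, size=(5, 3))
        frame = ref + rng.normal(0, 0.5, size=(5, 3))
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        frame = frame @ q + [4.0, 1.0, -2.0]
        # alignment over all five Cα; segment = residues 1..3
        got = evaluate_rc(_traj([frame], system), SegmentRmsd(0, 4, reference=ref))[0]
        expected = mda_rmsd(frame, ref, center=True, superposition=True)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_missing_calpha_rejected(self):
        system = make_bead_system(2)
        with pytest.raises(ValidationError, match="Cα"):
            evaluate_rc(_traj([np.zeros((2, 3))], system), CalphaDistance(0, 5))


class TestReweight:
    def test_zero_boost_is_unweighted_histogram(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 1.0, size=4000)
        surf = reweight(x, _boost(np.zeros(4000)), bin_size=0.5, cutoff=10)
        counts = surf.counts[surf.valid]
        expected = -KB * T * np.log(counts / counts.sum())
        expected -= expected.min()
        assert np.allclose(surf.pmf[surf.valid], expected, atol=1e-12)

    def test_constant_boost_equals_zero_boost(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5.0, 1.0, size=4000)
        a = reweight(x, _boost(np.zeros(4000)), bin_size=0.5, cutoff=10)
        b = reweight(x, _boost(np.full(4000, 3.7)), bin_size=0.5, cutoff=10)
        assert np.allclose(a.pmf[a.valid], b.pmf[b.valid], atol=1e-9)

    def test_exponential_equals_weighted_histogram_oracle(self):
        """Bit-for-bit agreement with an explicit per-frame accumulation."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(200, 800))
            x = rng.uniform(0, 6, size=n)
            dv = rng.uniform(0, 3, size=n)
            cutoff = int(rng.integers(1, 8))
            surf = reweight(x, _boost(dv), bin_size=0.5, cutoff=cutoff,
                            method="exponential")
            edges = surf.edges[0]
            nb = len(edges) - 1
            idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, nb - 1)
            sums = np.zeros(nb)
            counts = np.zeros(nb, dtype=int)
            for i, w in zip(idx, np.exp(BETA * dv)):
                sums[i] += w
                counts[i] += 1
            valid = counts >= cutoff
            pmf = np.full(nb, np.nan)
            pmf[valid] = -KB * T * np.log(sums[valid])
            pmf[valid] -= pmf[valid].min()
            assert np.array_equal(surf.valid, valid)
            assert np.array_equal(surf.pmf[valid], pmf[valid])

    @pytest.mark.parametrize("method", ["cumulant2", "exponential", "unweighted"])
    def test_shift_invariance(self, method):
        """Adding 7.3 kcal/mol to every ΔV leaves min-shifted PMFs unchanged.

        Exact for these methods: the constant factors out of the bin
        average (exponential), shifts only the first cumulant (cumulant2),
        or is ignored entirely (unweighted)."""
        rng = np.random.default_rng(3)
        x = rng.normal(4.0, 1.2, size=5000)
        dv = np.abs(rng.normal(2.0, 0.5, size=5000))
        a = reweight(x, _boost(dv), bin_size=0.5, cutoff=20, method=method)
        b = reweight(x, _boost(dv + 7.3), bin_size=0.5, cutoff=20, method=method)
        assert np.nanmax(np.abs(a.pmf[a.valid] - b.pmf[b.valid])) < 1e-9

    def test_maclaurin_shift_invariance_is_approached_with_order(self):
        """A truncated Maclaurin series is not exactly shift invariant (the
        constant cannot factor out of a finite polynomial); the violation
        must shrink as the truncation order grows."""
        rng = np.random.default_rng(4)
        x = rng.normal(4.0, 1.2, size=5000)
        dv = np.abs(rng.normal(2.0, 0.5, size=5000))
        errs = []
        for k in (10, 30, 80):
            a = reweight(x, _boost(dv), bin_size=0.5, cutoff=20,
                         method="maclaurin", maclaurin_k=k)
            b = reweight(x, _boost(dv + 7.3), bin_size=0.5, cutoff=20,
                         method="maclaurin", maclaurin_k=k)
            errs.append(np.nanmax(np.abs(a.pmf[a.valid] - b.pmf[b.valid])))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 1e-6

    def test_cumulant2_matches_exponential_for_gaussian_boost(self):
        """Second-order cumulant expansion is exact for Gaussian bin-local ΔV."""
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(2.0, 0.3, 5000), rng.normal(5.0, 0.3, 5000)])
        dv = np.abs(rng.normal(5.0, 0.6, size=10000))
        a = reweight(x, _boost(dv), bin_size=1.0, cutoff=1000, method="cumulant2")
        b = reweight(x, _boost(dv), bin_size=1.0, cutoff=1000, method="exponential")
        assert np.nanmax(np.abs(a.pmf[a.valid] - b.pmf[b.valid])) <= 0.2

    def test_cutoff_mask_exact_and_counts_conserved(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 2.0, size=3000)
        surf = reweight(x, _boost(np.zeros(3000)), bin_size=0.5, cutoff=50)
        assert surf.counts.sum() == 3000
        assert np.all(surf.counts[surf.valid] >= 50)
        assert np.all(surf.counts[~surf.valid] < 50)
        assert np.all(np.isnan(surf.pmf[~surf.valid]))
        assert np.nanmin(surf.pmf[surf.valid]) == 0.0

    def test_all_bins_below_cutoff_is_error(self):
        with pytest.raises(ValidationError, match="bin_size"):
            reweight(np.arange(10.0), _boost(np.zeros(10)), bin_size=0.5, cutoff=100)

    def test_2d_surface(self):
        rng = np.random.default_rng(7)
        x = rng.normal(3, 1, 5000)
        y = rng.normal(5, 1, 5000)
        surf = reweight((x, y), _boost(np.zeros(5000)), bin_size=1.0, cutoff=50)
        assert surf.ndim == 2
        assert surf.counts.sum() == 5000
        assert np.nanmin(surf.pmf[surf.valid]) == 0.0


class TestAnharmonicity:
    def test_gaussian_is_near_zero(self):
        rng = np.random.default_rng(0)
        gamma = anharmonicity(rng.normal(10, 2, size=100_000))
        assert gamma < 0.01

    def test_uniform_matches_analytic_entropy_deficit(self):
        """γ(uniform) = ½ ln(2πe/12) ≈ 0.1765 from the two closed-form
        differential entropies at matched variance."""
        rng = np.random.default_rng(1)
        gamma = anharmonicity(rng.uniform(0, 5, size=100_000))
        expected = 0.5 * math.log(2 * math.pi * math.e / 12.0)
        assert gamma == pytest.approx(expected, abs=0.02)

    def test_two_point_distribution_is_strongly_anharmonic(self):
        dv = np.array([0.0, 10.0] * 500)
        assert anharmonicity(dv, n_bins=50) > 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            anharmonicity(np.full(200, 3.0))


def _surface_1d(pmf, valid=None, bin_size=1.0):
    pmf = np.asarray(pmf, dtype=float)
    valid = np.ones(len(pmf), dtype=bool) if valid is None else np.asarray(valid)
    counts = np.where(valid, 1000, 0)
    p = pmf.copy()
    p[~valid] = np.nan
    edges = [np.arange(len(pmf) + 1, dtype=float) * bin_size]
    return FreeEnergySurface(edges=edges, pmf=p, counts=counts, valid=valid,
                             bin_size=bin_size, cutoff=100, method="cumulant2",
                             temperature=T)


class TestStateCounting:
    def test_single_basin(self):
        surf = _surface_1d([3.0, 1.2, 0.0, 1.1, 2.9])
        assert len(count_states(surf, 1.0)) == 1

    def test_two_wells_with_barrier(self):
        surf = _surface_1d([0.0, 0.4, 2.0, 0.6, 0.2])
        states = count_states(surf, 1.0)
        assert len(states) == 2

    def test_minimum_above_threshold_not_counted(self):
        surf = _surface_1d([0.0, 2.0, 1.5, 2.0, 3.0])
        assert len(count_states(surf, 1.0)) == 1   # the 1.5 minimum is above 1.0

    def test_plateau_collapses_to_one_state(self):
        surf = _surface_1d([0.0, 0.0, 0.0, 2.0])
        states = count_states(surf, 1.0)
        assert len(states) == 1
        assert states.states[0][0][0] == 0.5   # lowest-index bin center

    def test_invalid_bins_are_not_neighbors(self):
        valid = np.array([True, True, False, True, True])
        surf = _surface_1d([0.0, 0.5, np.nan, 0.6, 0.1], valid=valid)
        assert len(count_states(surf, 1.0)) == 2

    def test_2d_eight_neighborhood(self):
        pmf = np.full((5, 5), 3.0)
        pmf[1, 1] = 0.0
        pmf[3, 3] = 0.5
        valid = np.ones((5, 5), dtype=bool)
        counts = np.full((5, 5), 1000)
        surf = FreeEnergySurface(edges=[np.arange(6.0), np.arange(6.0)], pmf=pmf,
                                 counts=counts, valid=valid, bin_size=1.0,
                                 cutoff=100, method="cumulant2", temperature=T)
        assert len(count_states(surf, 1.0)) == 2


def test_surface_text_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    x = rng.normal(3, 1, 3000)
    for series in (x, (x, rng.normal(1, 0.5, 3000))):
        surf = reweight(series, _boost(np.abs(rng.normal(1, 0.2, 3000))),
                        bin_size=0.5, cutoff=20)
        path = tmp_path / "pmf.txt"
        write_surface(surf, path)
        back = read_surface(path)
        assert np.array_equal(back.valid, surf.valid)
        assert np.array_equal(back.counts, surf.counts)
        assert np.allclose(back.pmf[back.valid], surf.pmf[surf.valid], atol=1e-6)
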