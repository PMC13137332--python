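"""Spatial pattern metrics on hand-built snapshots."""

import numpy as np
import pytest

from crossrange.engine import Trajectory
from crossrange.metrics import (
    SuccessionPattern,
    UndefinedRatioError,
    classify_succession,
    frontier_fraction,
    growth_rate_ratio,
    inoculum_edge_fraction,
    intermixing_index,
    radial_abundance_profile,
)
from crossrange.scenario import ScenarioConfig

from conftest import make_snapshot


def ring(n, radius, species):
    """n cells of one species evenly spaced on a circle."""
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return (
        [species] * n,
        radius * np.cos(angles),
        radius * np.sin(angles),
    )


def combine(*groups):
    species, xs, ys = [], [], []
    for sp, x, y in groups:
        species.extend(sp)
        xs.extend(np.atleast_1d(x))
        ys.extend(np.atleast_1d(y))
    return species, xs, ys


class TestRadialProfile:
    def test_single_species_profile_is_one(self):
        snap = make_snapshot(*combine(ring(8, 3.0, "detoxifier"),
                                      ring(8, 5.0, "detoxifier")))
        prof = radial_abundance_profile(snap, bin_width=2.0)
        assert np.all(prof.detox_fraction[prof.occupied] == 1.0)

    def test_two_annuli_hand_counted(self):
        # annulus 1 (r ~ 2): 3 detox + 1 consumer; annulus 2 (r ~ 4): 1 + 3
        inner = combine(ring(3, 2.0, "detoxifier"), (["consumer"], [0.0], [2.0]))
        outer = combine((["detoxifier"], [4.0], [0.0]), ring(3, 4.2, "consumer"))
        snap = make_snapshot(*combine(inner, outer))
        prof = radial_abundance_profile(snap, bin_width=2.0)
        occ = prof.detox_fraction[prof.occupied]
        np.testing.assert_allclose(occ, [0.75, 0.25])

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        n = 60
        r = rng.uniform(1.5, 9, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        species = np.where(rng.random(n) < 0.5, "detoxifier", "consumer")
        base = radial_abundance_profile(
            make_snapshot(species, r * np.cos(phi), r * np.sin(phi))
        )
        rot = radial_abundance_profile(
            make_snapshot(species, r * np.cos(phi + 1.1), r * np.sin(phi + 1.1))
        )
        np.testing.assert_allclose(base.detox_fraction, rot.detox_fraction)

    def test_empty_snapshot_rejected(self):
        with pytest.raises(ValueError):
            radial_abundance_profile(make_snapshot([], [], []))

    def test_label_shuffle_concentrates_at_global_fraction(self):
        rng = np.random.default_rng(1)
        n = 3000
        r = np.sqrt(rng.uniform(1, 100, n))
        phi = rng.uniform(0, 2 * np.pi, n)
        species = np.where(rng.random(n) < 0.3, "detoxifier", "consumer")
        prof = radial_abundance_profile(
            make_snapshot(species, r * np.cos(phi), r * np.sin(phi)),
            bin_width=2.0,
        )
        frac = prof.detox_fraction[prof.counts > 50]
        assert np.all(np.abs(frac - 0.3) < 0.15)


class TestFrontierFraction:
    def test_all_consumers_in_band(self):
        snap = make_snapshot(*combine(ring(10, 2.0, "detoxifier"),
                                      ring(10, 8.0, "consumer")))
        assert frontier_fraction(snap, width=2.0) == 0.0

    def test_hand_counted_band(self):
        snap = make_snapshot(*combine(ring(3, 8.0, "detoxifier"),
                                      (["consumer"], [7.5], [0.1]),
                                      ring(6, 2.0, "consumer")))
        assert frontier_fraction(snap, width=2.0) == pytest.approx(0.75)

    def test_wide_band_equals_whole_colony_fraction(self):
        snap = make_snapshot(*combine(ring(4, 2.0, "detoxifier"),
                                      ring(12, 6.0, "consumer")))
        assert frontier_fraction(snap, width=100.0) == pytest.approx(4 / 16)


class TestIntermixing:
    def test_single_species_band_is_zero(self):
        snap = make_snapshot(*ring(12, 5.0, "detoxifier"))
        assert intermixing_index(snap, width=2.0) == 0.0

    def test_perfect_alternation_is_one(self):
        angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        species = ["detoxifier", "consumer"] * 5
        snap = make_snapshot(species, 5 * np.cos(angles), 5 * np.sin(angles))
        assert intermixing_index(snap, width=2.0) == pytest.approx(1.0)

    def test_two_blocks_give_two_transitions(self):
        angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        species = ["detoxifier"] * 5 + ["consumer"] * 5
        snap = make_snapshot(species, 5 * np.cos(angles), 5 * np.sin(angles))
        assert intermixing_index(snap, width=2.0) == pytest.approx(0.2)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        angles = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        labels = rng.random(40) < 0.4
        sp1 = np.where(labels, "detoxifier", "consumer")
        sp2 = np.where(labels, "consumer", "detoxifier")
        s1 = make_snapshot(sp1, 5 * np.cos(angles), 5 * np.sin(angles))
        s2 = make_snapshot(sp2, 5 * np.cos(angles), 5 * np.sin(angles))
        assert intermixing_index(s1, 2.0) == intermixing_index(s2, 2.0)

    def test_too_few_band_cells_rejected(self):
        snap = make_snapshot(["detoxifier"], [5.0], [0.0])
        with pytest.raises(ValueError):
            intermixing_index(snap, width=0.5)


class TestGrowthRateRatio:
    def test_equal_rates_give_unity(self):
        snap = make_snapshot(["detoxifier", "consumer"], [0, 1], [0, 0],
                             growth=[0.2, 0.2])
        assert growth_rate_ratio(snap) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        snap = make_snapshot(
            ["detoxifier", "detoxifier", "consumer"], [0, 1, 2], [0, 0, 0],
            growth=[0.3, 0.1, 0.1],
        )
        assert growth_rate_ratio(snap) == pytest.approx(2.0)

    def test_negative_consumer_mean_raises_with_pair(self):
        snap = make_snapshot(["detoxifier", "consumer"], [0, 1], [0, 0],
                             growth=[0.2, -0.05])
        with pytest.raises(UndefinedRatioError) as exc:
            growth_rate_ratio(snap)
        assert exc.value.pair == pytest.approx((0.2, -0.05))

    def test_absent_species_named_in_error(self):
        snap = make_snapshot(["detoxifier"], [0], [0])
        with pytest.raises(ValueError, match="consumer"):
            growth_rate_ratio(snap)


def synthetic_trajectory(fractions, radius_step=2.0, inoculum_radius=1.0):
    """Trajectory whose frontier band has the given detoxifier fractions."""
    snaps = []
    for k, f in enumerate(fractions):
        radius = inoculum_radius + radius_step * (k + 1)
        n_det = int(round(20 * f))
        groups = []
        if n_det:
            groups.append(ring(n_det, radius, "detoxifier"))
        if 20 - n_det:
            groups.append(ring(20 - n_det, radius * 0.999, "consumer"))
        groups.append(ring(10, inoculum_radius + 0.5, "consumer"))
        groups.append(ring(10, inoculum_radius + 0.6, "detoxifier"))
        snap = make_snapshot(*combine(*groups), time=float(k),
                             inoculum_radius=inoculum_radius)
        snaps.append(snap)
    return Trajectory(config=ScenarioConfig(), snapshots=snaps)


class TestClassifySuccession:
    def test_constant_half_is_simultaneous(self):
        traj = synthetic_trajectory([0.5] * 8)
        assert classify_succession(traj, band_width=1.0) is (
            SuccessionPattern.SIMULTANEOUS
        )

    def test_rising_and_holding_is_detoxifier_first(self):
        traj = synthetic_trajectory([0.5, 0.6, 0.7, 0.8, 0.9, 0.9, 0.9, 0.9])
        assert classify_succession(traj, band_width=1.0) is (
            SuccessionPattern.DETOXIFIER_FIRST
        )

    def test_falling_is_consumer_first(self):
        traj = synthetic_trajectory([0.5, 0.4, 0.3, 0.2, 0.1, 0.1, 0.1, 0.1])
        assert classify_succession(traj, band_width=1.0) is (
            SuccessionPattern.CONSUMER_FIRST
        )

    def test_short_trajectory_rejected(self):
        traj = synthetic_trajectory([0.5, 0.6])
        with pytest.raises(ValueError):
            classify_succession(traj)

    def test_invariant_to_time_rescaling(self):
        traj = synthetic_trajectory([0.5, 0.55, 0.7, 0.85, 0.9, 0.9, 0.92, 0.9])
        scaled = Trajectory(config=traj.config, snapshots=list(traj.snapshots))
        for snap in scaled.snapshots:
            snap.time *= 7.3
        assert classify_succession(traj, 1.0) == classify_succession(scaled, 1.0)


class TestInoculumEdgeFraction:
    def test_reads_first_occupied_bin(self):
        snap = make_snapshot(*combine(ring(4, 2.0, "detoxifier"),
                                      ring(4, 2.2, "consumer"),
                                      ring(10, 9.0, "detoxifier")),
                             inoculum_radius=1.0)
        assert inoculum_edge_fraction(snap, bin_width=2.0) == pytest.approx(0.5)
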