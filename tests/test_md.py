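"""Minimum-image distances, state classification, dwell and charge statistics."""

import numpy as np
import pandas as pd
import pytest

from claysorb.md import (
    ChargeSeries,
    TrajectoryFrame,
    classify_state,
    combine_replicate_tables,
    complex_charge,
    min_surface_distance,
    per_state_charge,
    ring_tilt_angle,
    state_series,
)

BOX = (41.44, 35.88, 62.5)


def frame_from(coords, roles, charges=None, ring=(0, 1, 2), box=BOX, time=0.0):
    coords = np.asarray(coords, dtype=float)
    charges = np.zeros(len(roles)) if charges is None else np.asarray(charges, float)
    return TrajectoryFrame(time, box, coords, tuple(roles), charges, tuple(ring))


def planar_ring(center, tilt_deg=0.0, radius=1.35):
    """Five-membered ring whose plane is tilted about y by tilt_deg."""
    t = np.radians(tilt_deg)
    ry = np.array(
        [[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]]
    )
    ring = np.array(
        [
            [radius * np.cos(2 * np.pi * k / 5), radius * np.sin(2 * np.pi * k / 5), 0.0]
            for k in range(5)
        ]
    )
    return ring @ ry.T + np.asarray(center)


def brute_force_min_distance(frame):
    """All-pairs, all-images oracle (positions wrapped to the primary cell)."""
    box = np.array(frame.box)
    coords = frame.coordinates % box
    shifts = [
        np.array([i, j, k]) * box
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
    ]
    best = np.inf
    for i in frame.indices("molecule"):
        for j in frame.indices("surface"):
            for s in shifts:
                best = min(best, float(np.linalg.norm(coords[i] - coords[j] + s)))
    return best


def brute_force_complex_charge(frame, cutoff=4.0):
    box = np.array(frame.box)
    coords = frame.coordinates % box
    mol = frame.indices("molecule")
    shifts = [
        np.array([i, j, k]) * box
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
    ]
    total = float(frame.charges[mol].sum())
    for role in ("cation", "anion"):
        for i in frame.indices(role):
            d = min(
                float(np.linalg.norm(coords[i] - coords[j] + s))
                for j in mol
                for s in shifts
            )
            if d <= cutoff:
                total += float(frame.charges[i])
    return total


class TestMinSurfaceDistance:
    def test_direct_distance(self):
        f = frame_from(
            [[0, 0, 5], [1, 0, 5], [0, 1, 5], [0, 0, 1]],
            ["molecule"] * 3 + ["surface"],
        )
        assert min_surface_distance(f) == pytest.approx(4.0)

    def test_wraparound_x(self):
        f = frame_from(
            [[1.0, 0, 5], [1.5, 0, 5], [1.0, 1, 5], [40.44, 0, 5]],
            ["molecule"] * 3 + ["surface"],
        )
        assert min_surface_distance(f) == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(10, 40))
            roles = ["molecule"] * 4 + ["surface"] * (n - 4)
            f = frame_from(rng.uniform(-30, 70, (n, 3)), roles, box=(12.0, 9.0, 15.0))
            assert min_surface_distance(f) == pytest.approx(
                brute_force_min_distance(f), abs=1e-10
            )

    def test_missing_role_rejected(self):
        f_roles = ["molecule"] * 4
        f = frame_from(np.zeros((4, 3)) + [[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 2, 2]], f_roles)
        with pytest.raises(ValueError, match="surface"):
            min_surface_distance(f)


class TestClassifyState:
    def _frame(self, dz, tilt):
        # anchor atom sits exactly dz above the surface atom; the ring floats higher
        ring = planar_ring([5.0, 5.0, 2.0 + dz], tilt)
        coords = np.vstack([ring, [[5.0, 5.0, 1.0 + dz]], [[5.0, 5.0, 1.0]]])
        return frame_from(coords, ["molecule"] * 6 + ["surface"], ring=(0, 1, 2, 3, 4))

    def test_cutoff_is_inclusive(self):
        # ring atoms tilted 0 deg, lowest ring atom exactly 4.0 A above the surface atom
        assert classify_state(self._frame(4.0, 0.0)) == 2

    def test_just_beyond_cutoff_is_free(self):
        assert classify_state(self._frame(4.05, 0.0)) == 0

    def test_parallel_vs_perpendicular(self):
        assert classify_state(self._frame(3.0, 0.0)) == 2
        assert classify_state(self._frame(3.0, 90.0)) == 1

    def test_collinear_ring_rejected(self):
        coords = np.array([[0, 0, 5], [1, 0, 5], [2, 0, 5], [0, 0, 1]], float)
        f = frame_from(coords, ["molecule"] * 3 + ["surface"])
        with pytest.raises(ValueError, match="collinear"):
            classify_state(f)

    def test_invariant_to_atom_order_and_box_translation(self):
        f = self._frame(3.0, 50.0)
        state = classify_state(f)
        # rigid translation by box-vector multiples
        shifted = frame_from(
            f.coordinates + np.array(BOX) * np.array([2, -1, 1]),
            f.roles, f.charges, f.ring_atoms,
        )
        assert classify_state(shifted) == state
        # atom reordering (reverse), remapping roles/ring indices
        n = len(f.roles)
        perm = np.arange(n)[::-1]
        inv = {old: new for new, old in enumerate(perm)}
        reordered = frame_from(
            f.coordinates[perm],
            [f.roles[i] for i in perm],
            f.charges[perm],
            tuple(inv[i] for i in f.ring_atoms),
        )
        assert classify_state(reordered) == state


class TestStateSeries:
    def _trajectory(self, states):
        """Frames engineered to classify as the given 0/1/2 sequence."""
        frames = []
        for k, s in enumerate(states):
            dz = 10.0 if s == 0 else 3.0
            tilt = 0.0 if s == 2 else (80.0 if s == 1 else 0.0)
            ring = planar_ring([5.0, 5.0, 1.0 + dz], tilt)
            coords = np.vstack([ring, [[5.0, 5.0, 1.0]]])
            frames.append(
                frame_from(coords, ["molecule"] * 5 + ["surface"], ring=(0, 1, 2, 3, 4),
                           time=0.1 * k)
            )
        return frames

    def test_duration_ratio_counting(self):
        frames = self._trajectory([1] * 40 + [0] * 100)
        series = state_series(frames)
        assert series.duration_ratio == pytest.approx(0.4)
        assert not series.ratio_infinite

    def test_all_adsorbed_gives_infinite_flag(self):
        frames = self._trajectory([2, 2, 1, 2])
        with pytest.warns(UserWarning, match="infinite"):
            series = state_series(frames)
        assert series.ratio_infinite
        assert series.duration_ratio == np.inf

    def test_dwell_segments_partition_time_axis(self):
        labels = [0, 0, 1, 1, 1, 0, 2, 2]
        series = state_series(self._trajectory(labels))
        segs = series.dwell_segments
        assert segs[0][1] == 0 and segs[-1][2] == len(labels)
        assert all(a[2] == b[1] for a, b in zip(segs, segs[1:]))
        rebuilt = np.concatenate([[s] * (b - a) for s, a, b in segs])
        assert rebuilt.tolist() == series.states.tolist()

    def test_min_dwell_relabels_fleeting_visits(self):
        labels = [0] * 10 + [1] + [0] * 10
        series = state_series(self._trajectory(labels), min_dwell_frames=3)
        assert set(series.states.tolist()) == {0}


class TestComplexCharge:
    def _ion_frame(self, n_near, n_far, ion_charge=1.0):
        mol = planar_ring([5.0, 5.0, 8.0])
        ions = [[5.0 + 2.5, 5.0, 8.0 + 0.1 * i] for i in range(n_near)]
        ions += [[25.0, 25.0, 40.0 + i] for i in range(n_far)]
        coords = np.vstack([mol, [[5.0, 5.0, 1.0]], ions])
        roles = ["molecule"] * 5 + ["surface"] + ["cation"] * (n_near + n_far)
        charges = np.concatenate(
            [[-0.4] * 5, [0.0], [ion_charge] * (n_near + n_far)]
        )
        return frame_from(coords, roles, charges, ring=(0, 1, 2, 3, 4))

    def test_three_bound_monovalent_cations(self):
        # molecule net -2 plus three monovalent cations within cutoff -> +1
        f = self._ion_frame(3, 4)
        assert complex_charge(f) == pytest.approx(1.0)

    def test_no_bound_ions_gives_molecule_net_charge(self):
        f = self._ion_frame(0, 5)
        assert complex_charge(f) == pytest.approx(-2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(14, 30))
            roles = (
                ["molecule"] * 4 + ["surface"] * (n - 8)
                + ["cation", "cation", "anion", "anion"]
            )
            f = frame_from(
                rng.uniform(-20, 40, (n, 3)), roles,
                rng.normal(0, 1, n), box=(11.0, 13.0, 9.0),
            )
            assert complex_charge(f) == pytest.approx(
                brute_force_complex_charge(f), abs=1e-10
            )


class TestPerStateCharge:
    def _series(self, states):
        states = np.asarray(states)
        n = len(states)
        from claysorb.md import StateSeries

        return StateSeries(
            states, np.zeros(n), np.zeros(n), np.arange(n, dtype=float),
            tuple(), 1.0, False,
        )

    def test_constant_charge(self):
        series = self._series([0, 1, 1, 2, 0])
        table = per_state_charge(series, ChargeSeries(np.full(5, 1.5)))
        for s in (0, 1, 2):
            assert table.loc[s, "mean"] == pytest.approx(1.5)
            assert table.loc[s, "sd"] == 0.0

    def test_unvisited_state_row_has_zero_n(self):
        series = self._series([0, 0, 1])
        table = per_state_charge(series, ChargeSeries(np.array([1.0, 1.0, 2.0])))
        assert table.loc[2, "n"] == 0
        assert np.isnan(table.loc[2, "mean"])

    def test_equal_frame_replicates_average_halfway(self):
        sa = self._series([1, 1])
        sb = self._series([1, 1])
        ta = per_state_charge(sa, ChargeSeries(np.array([1.0, 1.0])))
        tb = per_state_charge(sb, ChargeSeries(np.array([3.0, 3.0])))
        combined = combine_replicate_tables([ta, tb])
        assert combined.loc[1, "mean"] == pytest.approx(2.0)

    def test_frame_weighted_replicate_average(self):
        ta = per_state_charge(self._series([1]), ChargeSeries(np.array([1.0])))
        tb = per_state_charge(self._series([1, 1, 1]), ChargeSeries(np.array([3.0] * 3)))
        combined = combine_replicate_tables([ta, tb])
        assert combined.loc[1, "mean"] == pytest.approx((1.0 + 3.0 * 3) / 4)
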