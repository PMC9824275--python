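"""Contact analytics: oracle equivalence, boundary rules, classification."""

import numpy as np
import pandas as pd
import pytest

import nanofib as nf
from nanofib.contact_analysis import (
    ContactRecord,
    class_breakdown,
    classify_contact_type,
    contacts_in_frame,
    first_contact_time,
)
from nanofib.errors import (
    ConfigurationError,
    InputConsistencyError,
    InvalidArgumentError,
)
from nanofib.synthetic_data import Trajectory


def brute_force_contacts(coords, np_index, fib_index, box, cutoff):
    """O(N^2) minimum-image reference for contacting fibril beads."""
    hits = set()
    npb = coords[np_index]
    for jj, j in enumerate(fib_index):
        d = coords[j] - npb
        if box is not None:
            d = d - box * np.round(d / box)
        if (np.linalg.norm(d, axis=1) <= cutoff).any():
            hits.add(jj)
    return hits


def make_frame(fibril, np_positions, box=20.0):
    """System coords: fibril residues then NP beads."""
    boxv = np.full(3, box)
    fib = fibril.positions - fibril.positions.mean(0) + boxv / 2
    coords = np.concatenate([fib, np_positions])
    return coords, np.arange(len(fib)), np.arange(len(fib), len(coords)), boxv


class TestContactsInFrame:
    def test_far_nanoparticle_no_contacts(self, fibril):
        coords, fi, ni, box = make_frame(fibril, np.full((10, 3), 18.0))
        recs = contacts_in_frame(coords, ni, fibril, box=box, fibril_index=fi)
        assert recs == []

    def test_constructed_three_residue_contact(self, fibril):
        # one NP bead hovering 0.45 nm off residue V18 of chain 0 touches
        # the 17-19 stretch; the exact contact set must match brute force
        coords, fi, ni, box = make_frame(fibril, np.zeros((1, 3)))
        coords[ni[0]] = coords[fi[17]] + np.array([0.0, -0.45, 0.0])
        recs = contacts_in_frame(coords, ni, fibril, box=box, fibril_index=fi)
        got = {(r.chain, r.residue_index) for r in recs}
        oracle = brute_force_contacts(coords, ni, fi, box, 0.8)
        assert got == {
            (int(fibril.chain_of_residue[j]), int(fibril.residue_index[j]))
            for j in oracle
        }
        assert {17, 18, 19} <= {r.residue_index for r in recs}

    def test_boundary_is_closed(self, fibril):
        # a bead at exactly the cutoff distance counts as contact; use a
        # binary-exact cutoff so the boundary distance is representable
        coords, fi, ni, box = make_frame(fibril, np.zeros((1, 3)))
        coords[fi[0]] = np.array([10.0, 10.0, 10.0])
        coords[ni[0]] = np.array([10.0, 10.0, 10.75])
        recs = contacts_in_frame(
            coords, ni, fibril, cutoff=0.75, box=box, fibril_index=fi
        )
        assert any(r.chain == 0 and r.residue_index == 1 for r in recs)

    def test_component_mismatch_rejected(self, fibril):
        coords, fi, ni, box = make_frame(fibril, np.full((5, 3), 18.0))
        with pytest.raises(InputConsistencyError):
            contacts_in_frame(coords, ni, fibril, box=box, fibril_index=fi[:-3])

    def test_cutoff_monotonicity(self, fibril, rng):
        for _ in range(10):
            np_pos = rng.uniform(6, 14, size=(30, 3))
            coords, fi, ni, box = make_frame(fibril, np_pos)
            sets = []
            for cutoff in (0.5, 0.8, 1.5):
                recs = contacts_in_frame(
                    coords, ni, fibril, cutoff=cutoff, box=box, fibril_index=fi
                )
                sets.append({(r.chain, r.residue_index) for r in recs})
            assert sets[0] <= sets[1] <= sets[2]

    def test_oracle_equivalence_randomized(self, fibril, rng):
        for _ in range(30):
            center = rng.uniform(0, 20, 3)
            np_pos = center + rng.normal(scale=1.5, size=(25, 3))
            coords, fi, ni, box = make_frame(fibril, np_pos)
            recs = contacts_in_frame(coords, ni, fibril, box=box, fibril_index=fi)
            got = {(r.chain, r.residue_index) for r in recs}
            oracle = brute_force_contacts(coords, ni, fi, box, 0.8)
            assert got == {
                (int(fibril.chain_of_residue[j]), int(fibril.residue_index[j]))
                for j in oracle
            }

    def test_periodic_image_invariance(self, fibril, rng):
        np_pos = rng.uniform(8, 12, size=(20, 3))
        coords, fi, ni, box = make_frame(fibril, np_pos)
        base = contacts_in_frame(coords, ni, fibril, box=box, fibril_index=fi)
        base_set = {(r.chain, r.residue_index) for r in base}
        for shift in ([20, 0, 0], [0, -20, 0], [40, 20, -20]):
            moved = coords.copy()
            moved[ni] += np.asarray(shift, dtype=float)
            recs = contacts_in_frame(moved, ni, fibril, box=box, fibril_index=fi)
            assert {(r.chain, r.residue_index) for r in recs} == base_set


def _toy_trajectory(fibril, frames_np, box=20.0):
    boxv = np.full(3, box)
    fib = fibril.positions - fibril.positions.mean(0) + boxv / 2
    n_fib = len(fib)
    frames = np.array([np.concatenate([fib, f]) for f in frames_np])
    return Trajectory(
        times=np.arange(len(frames), dtype=float) * 10,
        frames=frames,
        box=boxv,
        fibril_index=np.arange(n_fib),
        np_index=np.arange(n_fib, n_fib + frames_np[0].shape[0]),
        masses=np.ones(n_fib + frames_np[0].shape[0]),
    )


class TestTimeseries:
    def test_no_binding_all_zero(self, fibril):
        traj = _toy_trajectory(fibril, [np.full((5, 3), 18.0)] * 4)
        ts = nf.contact_timeseries(traj, fibril)
        assert (ts["total"] == 0).all()

    def test_class_partition_every_frame(self, fibril, rng):
        frames = [rng.uniform(7, 13, size=(15, 3)) for _ in range(5)]
        traj = _toy_trajectory(fibril, frames)
        ts = nf.contact_timeseries(traj, fibril)
        assert (
            ts["hydrophobic"] + ts["polar"] + ts["charged"] == ts["total"]
        ).all()

    def test_matches_frame_by_frame_oracle(self, fibril, rng):
        frames = [rng.uniform(7, 13, size=(10, 3)) for _ in range(5)]
        traj = _toy_trajectory(fibril, frames)
        ts = nf.contact_timeseries(traj, fibril)
        for k in range(5):
            oracle = brute_force_contacts(
                traj.frames[k], traj.np_index, traj.fibril_index, traj.box, 0.8
            )
            assert ts["total"].iloc[k] == len(oracle)


class TestFirstContact:
    def test_all_zero_returns_none(self):
        assert first_contact_time(np.zeros(10)) is None

    def test_contact_from_first_frame(self):
        assert first_contact_time(np.ones(5), times=np.array([3.0, 4, 5, 6, 7])) == 3.0

    def test_persistence_skips_blip(self):
        series = np.zeros(50)
        series[3] = 2          # one-frame blip
        series[37:] = 4        # sustained contact
        times = np.arange(50, dtype=float)
        assert first_contact_time(series, persistence=5, times=times) == 37.0
        assert first_contact_time(series, persistence=1, times=times) == 3.0

    def test_exhaustive_scan_oracle(self, rng):
        for _ in range(50):
            series = (rng.uniform(size=20) < 0.4).astype(int)
            k = int(rng.integers(1, 5))
            got = first_contact_time(series, persistence=k)
            expected = None
            for s in range(21 - k):
                if all(series[s:s + k] > 0):
                    expected = float(s)
                    break
            assert got == expected

    def test_empty_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            first_contact_time(np.array([]))


class TestResidueFrequency:
    def test_bounds_and_extremes(self, fibril):
        # bead glued to residue 1 of chain 0 in every frame
        res0 = fibril.positions[0] - fibril.positions.mean(0) + 10.0
        frames = [res0[None, :] + [0, 0, 0.3]] * 6
        traj = _toy_trajectory(fibril, frames)
        freq = nf.residue_contact_frequency(traj, fibril)
        assert freq.loc[1] == 1.0
        assert freq.loc[30] == 0.0
        assert ((freq >= 0) & (freq <= 1)).all()

    def test_chain_aggregation_mode(self, fibril):
        res0 = fibril.positions[0] - fibril.positions.mean(0) + 10.0
        traj = _toy_trajectory(fibril, [res0[None, :]] * 3)
        freq = nf.residue_contact_frequency(traj, fibril, aggregate="chain")
        assert freq.loc[(0, 1)] == 1.0
        # chain-resolved frequencies are consistent with the position mode:
        # a position's any-chain frequency is at least each chain's own
        pos_freq = nf.residue_contact_frequency(traj, fibril)
        assert (freq.groupby("position").max() <= pos_freq + 1e-12).all()


def _records(*face_counts):
    """Build one frame of records: face_counts = [('side', n), ...]."""
    recs = []
    for face, n in face_counts:
        for i in range(n):
            recs.append(ContactRecord(0, 0, i + 1, 0.5, "hydrophobic", face))
    return recs


class TestClassify:
    def test_no_contacts_none(self):
        assert classify_contact_type([[], [], []]) == "none"

    def test_pure_frontal(self):
        assert classify_contact_type([_records(("frontal", 4))]) == "frontal"

    def test_pure_side(self):
        assert classify_contact_type([_records(("side", 4))]) == "side"

    def test_tie_breaks_to_side(self):
        recs = [_records(("frontal", 3), ("side", 3))]
        assert classify_contact_type(recs) == "side"

    def test_majority_after_first_contact(self):
        frames = [[], _records(("frontal", 1)), _records(("frontal", 5), ("side", 2))]
        assert classify_contact_type(frames) == "frontal"

    def test_missing_face_masks_rejected(self):
        recs = [[ContactRecord(0, 0, 1, 0.5, "polar", "")]]
        with pytest.raises(ConfigurationError):
            classify_contact_type(recs)


class TestClassBreakdown:
    def test_aromatic_pair_counts_hydrophobic(self, fibril):
        sel = [
            j for j in range(fibril.n_residues)
            if fibril.residue_index[j] in (19, 20) and fibril.chain_of_residue[j] == 0
        ]
        recs = [
            ContactRecord(0, 0, int(fibril.residue_index[j]), 0.5,
                          str(fibril.classes[j]), "side")
            for j in sel
        ]
        counts = class_breakdown(recs)
        assert counts == {"hydrophobic": 2, "polar": 0, "charged": 0}

    def test_empty_records_all_zero(self):
        assert class_breakdown([]) == {"hydrophobic": 0, "polar": 0, "charged": 0}

    def test_mixed_tally_matches_oracle(self, fibril, rng):
        idx = rng.choice(fibril.n_residues, 40, replace=False)
        recs = [
            ContactRecord(0, int(fibril.chain_of_residue[j]),
                          int(fibril.residue_index[j]), 0.4,
                          str(fibril.classes[j]), "side")
            for j in idx
        ]
        counts = class_breakdown(recs)
        expected = {
            c: int((fibril.classes[idx] == c).sum())
            for c in ("hydrophobic", "polar", "charged")
        }
        assert counts == expected
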