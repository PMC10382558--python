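"""Pore metrics vs independent brute-force oracles on synthetic trajectories."""

import numpy as np
import pandas as pd
import pytest

from kirgate.md_traj import (
    CylinderSpec, TrajectoryFrames, FRAME_COLUMNS,
    read_frames, com, in_cylinder, pore_trace, count_permeations,
    occupancy_histogram, min_cross_subunit_distance, synth_trajectory,
    sf_bounds, K_CYLINDER, SF_RADIUS,
)


# ---------------------------------------------------------------------------
# independent brute-force oracles


def oracle_permeations(traj) -> int:
    z_lo, z_hi, cxy = sf_bounds(traj)
    total = 0
    sel = traj.df[traj.df["tag"] == "K"]
    for pid in sel["id"].unique():
        p = sel[sel["id"] == pid].sort_values("frame")[["x", "y", "z"]]\
            .to_numpy()
        occupying = False
        for f in range(len(p)):
            r = np.hypot(p[f, 0] - cxy[f, 0], p[f, 1] - cxy[f, 1])
            if r <= SF_RADIUS and z_lo[f] <= p[f, 2] <= z_hi[f]:
                occupying = True
            elif p[f, 2] > z_hi[f]:
                if occupying:
                    total += 1
                occupying = False
            elif p[f, 2] < z_lo[f]:
                occupying = False
    return total


def oracle_pore_membership(traj, group="K"):
    spec = K_CYLINDER
    rows = []
    for f in traj.frames:
        fr = traj.frame(f)
        c = com(fr, spec.center_tag)
        for _, p in fr[fr["tag"] == group].iterrows():
            r = np.hypot(p["x"] - c[0], p["y"] - c[1])
            if r <= spec.radius and abs(p["z"] - c[2]) <= spec.height / 2:
                rows.append((f, p["id"], p["z"]))
    return set((int(a), int(b)) for a, b, _ in rows)


def oracle_min_dist(traj, tag, ca, cb):
    out = []
    for f in traj.frames:
        fr = traj.frame(f)
        a = fr[(fr["tag"] == tag) & (fr["chain"] == ca)][["x", "y", "z"]]\
            .to_numpy()
        b = fr[(fr["tag"] == tag) & (fr["chain"] == cb)][["x", "y", "z"]]\
            .to_numpy()
        best = np.inf
        for pa in a:
            for pb in b:
                best = min(best, float(np.linalg.norm(pa - pb)))
        out.append(best)
    return np.array(out)


# ---------------------------------------------------------------------------


def _tiny_frames(records, interval=1000.0):
    df = pd.DataFrame(records, columns=list(FRAME_COLUMNS))
    return TrajectoryFrames(df=df, frame_interval_ps=interval,
                            box=(4.0, 4.0, 12.0))


class TestTrajectoryFrames:
    def test_round_trip(self, tmp_path):
        traj = synth_trajectory(n_ions=3, n_frames=4, seed=1)
        p = tmp_path / "traj.tsv"
        traj.to_tsv(p)
        back = read_frames(p)
        pd.testing.assert_frame_equal(back.df, traj.df)
        assert back.frame_interval_ps == traj.frame_interval_ps

    def test_frame_gap_rejected(self):
        recs = [(0, 1, "K", "-", 0, 0, 1.0), (2, 1, "K", "-", 0, 0, 1.1)]
        with pytest.raises(ValueError, match="contiguous"):
            _tiny_frames(recs)

    def test_unstable_ids_rejected(self):
        recs = [(0, 1, "K", "-", 0, 0, 1.0), (1, 2, "K", "-", 0, 0, 1.0)]
        with pytest.raises(ValueError, match="stable"):
            _tiny_frames(recs)

    def test_missing_column_reported(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({"frame": [0], "id": [1], "x": [0.0]}).to_csv(
            p, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            read_frames(p)


class TestGeometry:
    def test_com_single_and_symmetric(self):
        recs = [(0, 1, "M181", "A", 1.0, 1.0, 0.0),
                (0, 2, "M181", "B", -1.0, 1.0, 0.0),
                (0, 3, "M181", "C", -1.0, -1.0, 0.0),
                (0, 4, "M181", "D", 1.0, -1.0, 0.0),
                (0, 5, "K", "-", 0.4, 0.0, 0.2)]
        traj = _tiny_frames(recs)
        np.testing.assert_allclose(com(traj.frame(0), "M181"),
                                   [0.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(com(traj.frame(0), "M181", chain="A"),
                                   [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="empty group"):
            com(traj.frame(0), "nope")

    def test_in_cylinder_boundary_closed(self):
        spec = CylinderSpec(center_tag="M181", height=2.0, radius=1.0)
        base = [(0, 1, "M181", "A", 0.0, 0.0, 0.0)]
        inside = _tiny_frames(base + [(0, 9, "K", "-", 1.0, 0.0, 0.0)])
        assert in_cylinder(inside.frame(0), 9, spec)  # r == radius
        outside = _tiny_frames(base + [(0, 9, "K", "-", 1.0001, 0.0, 0.0)])
        assert not in_cylinder(outside.frame(0), 9, spec)
        above = _tiny_frames(base + [(0, 9, "K", "-", 0.0, 0.0, 1.0001)])
        assert not in_cylinder(above.frame(0), 9, spec)


class TestPoreTrace:
    def test_membership_matches_oracle(self):
        for seed in range(5):
            traj = synth_trajectory(n_ions=8, n_frames=30, seed=seed,
                                    pore_radius=3.0, step_sd=0.4)
            got = set(map(tuple, pore_trace(traj, "K")[["frame", "id"]]
                          .to_numpy()))
            assert got == oracle_pore_membership(traj)

    def test_radially_outside_particle_absent(self):
        traj = synth_trajectory(n_ions=0, n_frames=6, seed=0,
                                pore_radius=3.0)
        nid = traj.df["id"].max() + 1
        extra = [(f, nid + j, "K", "-", x, 0.0, 6.0)
                 for f in range(6)
                 for j, x in enumerate([2.9, 1.5])]  # outside/inside 2.5 nm
        df = pd.concat([traj.df, pd.DataFrame(
            extra, columns=list(FRAME_COLUMNS))], ignore_index=True)
        traj2 = TrajectoryFrames(df=df, frame_interval_ps=1000.0,
                                 box=traj.box)
        pt = pore_trace(traj2, "K")
        assert set(pt["id"]) == {nid + 1}
        assert len(pt) == 6


class TestPermeations:
    def test_scripted_single_passage(self):
        # SF spans z in [zc+2.0, zc+2.5] with zc = 6; ion rises through it
        zs = [7.0, 8.2, 9.5]
        recs = []
        for f, z in enumerate(zs):
            for i, (tag, chain, x, y, zz) in enumerate([
                    ("T143O", "A", 0.1, 0.0, 8.0),
                    ("T143O", "C", -0.1, 0.0, 8.0),
                    ("Y146O", "A", 0.1, 0.0, 8.5),
                    ("Y146O", "C", -0.1, 0.0, 8.5)]):
                recs.append((f, i, tag, chain, x, y, zz))
            recs.append((f, 99, "K", "-", 0.0, 0.0, z))
        traj = _tiny_frames(recs)
        assert count_permeations(traj).total == 1

    def test_oscillation_below_never_counts(self):
        recs = []
        for f, z in enumerate([7.0, 7.9, 7.0, 7.9, 7.0]):
            for i, (tag, chain, zz) in enumerate([("T143O", "A", 8.0),
                                                  ("T143O", "C", 8.0),
                                                  ("Y146O", "A", 8.5),
                                                  ("Y146O", "C", 8.5)]):
                recs.append((f, i, tag, chain, 0.1 if i % 2 else -0.1,
                             0.0, zz))
            recs.append((f, 99, "K", "-", 0.0, 0.0, z))
        traj = _tiny_frames(recs)
        assert count_permeations(traj).total == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        traj = synth_trajectory(n_ions=12, n_frames=40, seed=seed,
                                pore_radius=0.4, step_sd=0.5, drift=0.1)
        assert count_permeations(traj).total == oracle_permeations(traj)

    def test_upward_drift_produces_flux(self):
        traj = synth_trajectory(n_ions=40, n_frames=120, seed=5,
                                pore_radius=0.3, step_sd=0.3, drift=0.6)
        pc = count_permeations(traj)
        assert pc.total > 0
        assert pc.rate_per_us == pytest.approx(
            pc.total / (120 * 1000.0 * 1e-6))

    def test_symmetric_walk_balanced_crossings(self):
        """Zero drift: net upward minus downward crossings of the SF top
        boundary stays within counting noise."""
        traj = synth_trajectory(n_ions=30, n_frames=150, seed=7,
                                pore_radius=0.4, step_sd=0.4, drift=0.0)
        _, z_hi, _ = sf_bounds(traj)
        sel = traj.df[traj.df["tag"] == "K"]
        ups = downs = 0
        for pid in sel["id"].unique():
            z = sel[sel["id"] == pid].sort_values("frame")["z"].to_numpy()
            above = z > z_hi
            ups += int(((~above[:-1]) & above[1:]).sum())
            downs += int((above[:-1] & (~above[1:])).sum())
        assert abs(ups - downs) <= max(3 * np.sqrt(ups + downs), 3)


class TestOccupancyHistogram:
    def test_static_ion_counts_one(self):
        traj = synth_trajectory(n_ions=0, n_frames=5, seed=0)
        zc = 6.0
        extra = []
        nid = traj.df["id"].max() + 1
        for f in range(5):
            extra.append((f, nid, "K", "-", 0.0, 0.0, zc + 1.0))
        df = pd.concat([traj.df, pd.DataFrame(
            extra, columns=list(FRAME_COLUMNS))], ignore_index=True)
        traj2 = TrajectoryFrames(df=df, frame_interval_ps=1000.0,
                                 box=traj.box)
        centers, counts, pool = occupancy_histogram(traj2)
        assert pool == pytest.approx(1.0)
        assert counts.sum() == 5

    def test_histogram_total_equals_membership(self):
        traj = synth_trajectory(n_ions=10, n_frames=50, seed=3,
                                pore_radius=1.5)
        _, counts, _ = occupancy_histogram(traj)
        assert counts.sum() == len(pore_trace(traj, "K"))

    def test_uniform_cloud_mean_count(self):
        """Uniform walker density: mean pool count ~= density x region.

        A short box and large steps keep the reflected walk well mixed so
        the time-averaged density is uniform to within the tolerance."""
        traj = synth_trajectory(n_ions=60, n_frames=400, seed=11,
                                pore_radius=1.0, step_sd=1.0, box_z=8.0)
        _, _, pool = occupancy_histogram(traj)
        # pool region: z between M308 (zc-2) and SF lower bound (zc+2)
        expected = 60 * 4.0 / 8.0
        assert pool == pytest.approx(expected, rel=0.15)


class TestMinDistance:
    def test_two_single_atoms(self):
        recs = [(0, 1, "I177", "A", 0.41, 0.0, 0.0),
                (0, 2, "I177", "C", -0.41, 0.0, 0.0),
                (0, 3, "I177", "B", 0.0, 0.41, 0.0),
                (0, 4, "I177", "D", 0.0, -0.41, 0.0)]
        traj = _tiny_frames(recs)
        res = min_cross_subunit_distance(traj, "I177")
        assert res["per_pair"][("A", "C")][0] == pytest.approx(0.82)
        assert res["mode"] == pytest.approx(0.82, abs=0.01)

    def test_far_atom_does_not_change_minimum(self):
        near = [(0, 1, "I177", "A", 0.41, 0.0, 0.0),
                (0, 2, "I177", "C", -0.41, 0.0, 0.0),
                (0, 3, "I177", "B", 0.0, 0.41, 0.0),
                (0, 4, "I177", "D", 0.0, -0.41, 0.0)]
        far = near + [(0, 5, "I177", "A", 3.0, 3.0, 3.0)]
        a = min_cross_subunit_distance(_tiny_frames(near), "I177")
        b = min_cross_subunit_distance(_tiny_frames(far), "I177")
        assert b["per_pair"][("A", "C")][0] == \
            a["per_pair"][("A", "C")][0]

    def test_missing_chain_rejected(self):
        recs = [(0, 1, "I177", "A", 0.4, 0.0, 0.0)]
        with pytest.raises(ValueError, match="absent"):
            min_cross_subunit_distance(_tiny_frames(recs), "I177")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        recs = []
        for f in range(6):
            i = 0
            for chain in "ABCD":
                for _ in range(4):
                    x, y, z = rng.normal(0, 1.0, 3)
                    recs.append((f, i, "M181", chain, x, y, z))
                    i += 1
        traj = _tiny_frames(recs)
        res = min_cross_subunit_distance(traj, "M181")
        for ca, cb in (("A", "C"), ("B", "D")):
            np.testing.assert_allclose(res["per_pair"][(ca, cb)],
                                       oracle_min_dist(traj, "M181",
                                                       ca, cb),
                                       atol=1e-12)


class TestInvariances:
    def test_rigid_xy_translation(self):
        traj = synth_trajectory(n_ions=10, n_frames=30, seed=9,
                                pore_radius=0.5, step_sd=0.3, drift=0.2)
        shifted_df = traj.df.copy()
        shifted_df["x"] += 5.0
        shifted_df["y"] -= 3.0
        shifted = TrajectoryFrames(df=shifted_df, frame_interval_ps=1000.0,
                                   box=traj.box)
        assert count_permeations(traj).total == \
            count_permeations(shifted).total
        assert len(pore_trace(traj, "K")) == len(pore_trace(shifted, "K"))

    def test_coordinate_scaling_scales_distances(self):
        traj = synth_trajectory(n_ions=4, n_frames=10, seed=13)
        scaled_df = traj.df.copy()
        for col in ("x", "y", "z"):
            scaled_df[col] *= 2.0
        scaled = TrajectoryFrames(df=scaled_df, frame_interval_ps=1000.0,
                                  box=tuple(2 * b for b in traj.box))
        a = min_cross_subunit_distance(traj, "I177")
        b = min_cross_subunit_distance(scaled, "I177")
        np.testing.assert_allclose(b["per_pair"][("A", "C")],
                                   2 * a["per_pair"][("A", "C")],
                                   atol=1e-12)


class TestSynthTrajectory:
    def test_seed_determinism(self, tmp_path):
        a = synth_trajectory(n_ions=5, n_frames=20, seed=21)
        b = synth_trajectory(n_ions=5, n_frames=20, seed=21)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_wrapped_coordinates_warn(self):
        traj = synth_trajectory(n_ions=1, n_frames=3, seed=1)
        df = traj.df.copy()
        kid = df[df["tag"] == "K"]["id"].iloc[0]
        df.loc[(df["id"] == kid) & (df["frame"] == 1), "z"] = 0.1
        df.loc[(df["id"] == kid) & (df["frame"] == 2), "z"] = 11.9
        bad = TrajectoryFrames(df=df, frame_interval_ps=1000.0,
                               box=traj.box)
        with pytest.warns(RuntimeWarning, match="wrapped"):
            count_permeations(bad)
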