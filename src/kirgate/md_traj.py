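"""Pore metrics on labeled particle trajectories.

Implements the trajectory-analysis machinery used to characterize K+
permeation and pore geometry in Kir2 channel simulations:

* selection cylinders centered per frame on the center of the M181 gate
  residues (height 11 nm; radius 2.5 nm for K+, 1 nm for water), plus a
  narrow selectivity-filter (SF) cylinder spanning the T143--Y146
  backbone-oxygen centers with a 0.25 nm radius,
* per-particle z-vs-frame pore traces for flux and solvation plots,
* conduction-event counting: an ion that occupied the SF cylinder and then
  exits across its upper (extracellular, +z) boundary scores one event,
* z-occupancy histograms (0.05 nm bins) and the mean K+ count pooled
  between the SF and the M308 G-loop constriction,
* per-frame minimum atom distances between opposing subunits (chain pairs
  A--C and B--D) for gate-diameter histograms,
* a seeded synthetic trajectory generator (random walk in a reflective
  cylinder with optional axial drift) serving as the test oracle.

Centers are geometric (unweighted) since the frames dialect carries no
masses.  Coordinates are assumed unwrapped along z; a per-frame jump
larger than half the box height triggers a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRAME_COLUMNS = ("frame", "id", "tag", "chain", "x", "y", "z")


@dataclass
class TrajectoryFrames:
    """Per-frame labeled particle coordinates.

    ``df`` holds columns frame, id, tag, chain, x, y, z (nm); particle ids
    must be present in every frame.  ``frame_interval_ps`` is the time
    between stored frames.
    """

    df: pd.DataFrame
    frame_interval_ps: float
    box: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        missing = set(FRAME_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"frames table missing columns {sorted(missing)}")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be > 0")
        xyz = self.df[["x", "y", "z"]].to_numpy(float)
        if not np.isfinite(xyz).all():
            raise ValueError("non-finite coordinates")
        frames = np.sort(self.df["frame"].unique())
        if len(frames) > 1 and not np.array_equal(
                frames, np.arange(frames[0], frames[0] + len(frames))):
            raise ValueError("frame indices must be contiguous")
        ids0 = None
        for f, grp in self.df.groupby("frame"):
            ids = frozenset(grp["id"])
            if ids0 is None:
                ids0 = ids
            elif ids != ids0:
                raise ValueError(
                    f"particle id set changes at frame {f}; ids must be "
                    "stable across frames")
        self.df = self.df.sort_values(["frame", "id"], kind="stable"
                                      ).reset_index(drop=True)
        self._frames = frames

    @property
    def n_frames(self) -> int:
        return len(self._frames)

    @property
    def frames(self) -> np.ndarray:
        return self._frames

    def frame(self, f: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == f]

    def group(self, f: int, tag: str, chain: str | None = None
              ) -> pd.DataFrame:
        g = self.frame(f)
        g = g[g["tag"] == tag]
        if chain is not None:
            g = g[g["chain"] == chain]
        return g

    def to_tsv(self, path, sidecar: bool = True) -> None:
        self.df.to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {"frame_interval_ps": self.frame_interval_ps,
                    "box": list(self.box), "label": self.label}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)


@dataclass(frozen=True)
class CylinderSpec:
    """Axis-aligned (z) analysis cylinder centered on a tagged group's COM."""

    center_tag: str = "M181"
    height: float = 11.0   # nm
    radius: float = 2.5    # nm

    def __post_init__(self) -> None:
        if self.height <= 0 or self.radius <= 0:
            raise ValueError("height and radius must be > 0")


K_CYLINDER = CylinderSpec(center_tag="M181", height=11.0, radius=2.5)
WATER_CYLINDER = CylinderSpec(center_tag="M181", height=11.0, radius=1.0)
SF_RADIUS = 0.25           # nm
SF_LOWER_TAG = "T143O"     # backbone-oxygen group bounding the SF below
SF_UPPER_TAG = "Y146O"     # and above (extracellular side)


@dataclass
class PermeationCount:
    """Completed upward SF exits per trajectory."""

    events: list[tuple[int, int]]  # (particle id, crossing frame)
    n_frames: int
    frame_interval_ps: float

    @property
    def total(self) -> int:
        return len(self.events)

    @property
    def rate_per_us(self) -> float:
        span_us = self.n_frames * self.frame_interval_ps * 1e-6
        return self.total / span_us if span_us > 0 else np.nan


# ---------------------------------------------------------------------------
# IO


def read_frames(path, frame_interval_ps: float | None = None,
                box: tuple[float, float, float] | None = None,
                label: str = "") -> TrajectoryFrames:
    """Read a frames table (TSV) plus optional sidecar JSON metadata."""
    try:
        df = pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise FileNotFoundError(f"frames table not found: {path}")
    missing = set(FRAME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required columns {sorted(missing)} "
            "(header is line 1)")
    import os
    sidecar = str(path) + ".json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
        frame_interval_ps = meta.get("frame_interval_ps", frame_interval_ps)
        box = tuple(meta.get("box", box or (10.0, 10.0, 12.0)))
        label = meta.get("label", label)
    if frame_interval_ps is None:
        frame_interval_ps = 1000.0
    if box is None:
        box = (10.0, 10.0, 12.0)
    return TrajectoryFrames(df=df, frame_interval_ps=frame_interval_ps,
                            box=tuple(box), label=label)


# ---------------------------------------------------------------------------
# geometry primitives


def com(frame_df: pd.DataFrame, tag: str,
        chain: str | None = None) -> np.ndarray:
    """Geometric center of a tagged group in one frame."""
    g = frame_df[frame_df["tag"] == tag]
    if chain is not None:
        g = g[g["chain"] == chain]
    if len(g) == 0:
        raise ValueError(f"empty group: tag={tag!r}, chain={chain!r}")
    return g[["x", "y", "z"]].to_numpy(float).mean(axis=0)


def in_cylinder(frame_df: pd.DataFrame, particle_id, spec: CylinderSpec
                ) -> bool:
    """Closed-boundary membership of a particle in an analysis cylinder."""
    row = frame_df[frame_df["id"] == particle_id]
    if len(row) != 1:
        raise ValueError(f"particle {particle_id} not unique in frame")
    p = row[["x", "y", "z"]].to_numpy(float)[0]
    c = com(frame_df, spec.center_tag)
    r = np.hypot(p[0] - c[0], p[1] - c[1])
    return bool(r <= spec.radius
                and c[2] - spec.height / 2 <= p[2] <= c[2] + spec.height / 2)


def _group_positions(traj: TrajectoryFrames, tag: str
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(ids, positions[n_frames, n_particles, 3]) for one tag, frame-ordered."""
    sel = traj.df[traj.df["tag"] == tag]
    ids = np.sort(sel["id"].unique())
    n_f, n_p = traj.n_frames, len(ids)
    pos = (sel.sort_values(["frame", "id"], kind="stable")
           [["x", "y", "z"]].to_numpy(float).reshape(n_f, n_p, 3))
    return ids, pos


def _center_series(traj: TrajectoryFrames, tag: str) -> np.ndarray:
    """Per-frame geometric center of a tagged group, (n_frames, 3)."""
    sel = traj.df[traj.df["tag"] == tag]
    if len(sel) == 0:
        raise ValueError(f"no particles tagged {tag!r}")
    g = sel.groupby("frame")[["x", "y", "z"]].mean()
    return g.to_numpy(float)


def _warn_on_z_jumps(pos_z: np.ndarray, box_z: float) -> None:
    if pos_z.shape[0] > 1:
        jumps = np.abs(np.diff(pos_z, axis=0))
        if (jumps > box_z / 2).any():
            warnings.warn(
                "z jump larger than half the box between frames: "
                "coordinates may be wrapped; permeation counts unreliable",
                RuntimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# pore metrics


def pore_trace(traj: TrajectoryFrames, group: str = "K") -> pd.DataFrame:
    """Per-frame z of every group particle inside its selection cylinder.

    Cylinder: 2.5 nm radius for K+, 1 nm for water oxygens, 11 nm height,
    centered on the M181 COM.  Returns a long table (frame, id, z).
    """
    spec = K_CYLINDER if group == "K" else WATER_CYLINDER
    ids, pos = _group_positions(traj, group)
    centers = _center_series(traj, spec.center_tag)
    dx = pos[:, :, 0] - centers[:, None, 0]
    dy = pos[:, :, 1] - centers[:, None, 1]
    r = np.hypot(dx, dy)
    z = pos[:, :, 2]
    inside = (r <= spec.radius) & \
        (np.abs(z - centers[:, None, 2]) <= spec.height / 2)
    f_idx, p_idx = np.nonzero(inside)
    return pd.DataFrame({"frame": traj.frames[f_idx],
                         "id": ids[p_idx],
                         "z": z[f_idx, p_idx]})


def sf_bounds(traj: TrajectoryFrames) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lower z, upper z, xy center) of the SF cylinder per frame."""
    lo = _center_series(traj, SF_LOWER_TAG)
    hi = _center_series(traj, SF_UPPER_TAG)
    center_xy = 0.5 * (lo[:, :2] + hi[:, :2])
    return lo[:, 2], hi[:, 2], center_xy


def count_permeations(traj: TrajectoryFrames, group: str = "K"
                      ) -> PermeationCount:
    """Count completed outward (upward) conduction events through the SF.

    Per-ion state machine: an ion becomes SF-occupying when it is found
    inside the SF cylinder (between the T143 and Y146 backbone-oxygen
    center z-levels, within 0.25 nm of the filter axis) while below the
    upper boundary; a conduction event fires when the ion subsequently
    crosses above the upper boundary into the extracellular solvent.
    Falling back below the SF resets the ion.
    """
    ids, pos = _group_positions(traj, group)
    z_lo, z_hi, cxy = sf_bounds(traj)
    _warn_on_z_jumps(pos[:, :, 2], traj.box[2])
    r = np.hypot(pos[:, :, 0] - cxy[:, None, 0],
                 pos[:, :, 1] - cxy[:, None, 1])
    z = pos[:, :, 2]
    in_sf = (r <= SF_RADIUS) & (z >= z_lo[:, None]) & (z <= z_hi[:, None])
    above = z > z_hi[:, None]
    below = z < z_lo[:, None]

    events: list[tuple[int, int]] = []
    for j, pid in enumerate(ids):
        occupying = False
        for f in range(traj.n_frames):
            if in_sf[f, j]:
                occupying = True
            elif above[f, j]:
                if occupying:
                    events.append((int(pid), int(traj.frames[f])))
                occupying = False
            elif below[f, j]:
                occupying = False
    return PermeationCount(events=events, n_frames=traj.n_frames,
                           frame_interval_ps=traj.frame_interval_ps)


def occupancy_histogram(traj: TrajectoryFrames, group: str = "K",
                        bin_width: float = 0.05
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """z-histogram of in-pore ions and the mean SF--M308 pool count.

    Returns (bin centers, counts, mean per-frame count of group particles
    with z between the M308 COM and the SF lower boundary).
    """
    pt = pore_trace(traj, group)
    z_lo, _, _ = sf_bounds(traj)
    m308_z = _center_series(traj, "M308")[:, 2]
    if len(pt) == 0:
        return np.array([]), np.array([]), 0.0
    zmin = np.floor(pt["z"].min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((pt["z"].max() - zmin) / bin_width)))
    counts, edges = np.histogram(pt["z"], bins=n_bins,
                                 range=(zmin, zmin + n_bins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])

    frame_pos = {f: i for i, f in enumerate(traj.frames)}
    fi = pt["frame"].map(frame_pos).to_numpy()
    zz = pt["z"].to_numpy()
    in_pool = (zz >= m308_z[fi]) & (zz <= z_lo[fi])
    pool_per_frame = np.bincount(fi[in_pool], minlength=traj.n_frames)
    return centers, counts, float(pool_per_frame.mean())


def min_cross_subunit_distance(traj: TrajectoryFrames, residue_tag: str,
                               chain_pairs=(("A", "C"), ("B", "D")),
                               bin_width: float = 0.01
                               ) -> dict:
    """Per-frame minimum atom distance between opposing subunits.

    For each opposing chain pair the minimum pairwise distance between the
    residue's atoms is computed per frame; a pooled histogram (default
    0.1 angstrom = 0.01 nm bins) and its modal value are reported.
    Distances are in nm.
    """
    sel = traj.df[traj.df["tag"] == residue_tag]
    per_pair = {}
    for ca, cb in chain_pairs:
        a = sel[sel["chain"] == ca]
        b = sel[sel["chain"] == cb]
        if len(a) == 0 or len(b) == 0:
            raise ValueError(
                f"residue {residue_tag!r} absent on chain "
                f"{ca if len(a) == 0 else cb!r}")
        dists = np.empty(traj.n_frames)
        for i, f in enumerate(traj.frames):
            pa = a[a["frame"] == f][["x", "y", "z"]].to_numpy(float)
            pb = b[b["frame"] == f][["x", "y", "z"]].to_numpy(float)
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            dists[i] = d.min()
        per_pair[(ca, cb)] = dists
    pooled = np.concatenate(list(per_pair.values()))
    lo = np.floor(pooled.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((pooled.max() - lo) / bin_width)) + 1)
    counts, edges = np.histogram(pooled, bins=n_bins,
                                 range=(lo, lo + n_bins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[np.argmax(counts)])
    return {"per_pair": per_pair, "bin_centers": centers,
            "counts": counts, "mode": mode}


# ---------------------------------------------------------------------------
# synthetic trajectory generator


def synth_trajectory(n_ions: int = 20, n_waters: int = 0,
                     n_frames: int = 200, drift: float = 0.0,
                     step_sd: float = 0.15, seed: int = 0,
                     pore_radius: float = 2.0, box_z: float = 12.0,
                     frame_interval_ps: float = 1000.0,
                     label: str = "synthetic") -> TrajectoryFrames:
    """Random-walk particles in a reflective cylinder around fixed markers.

    Emulates a pore-shaped system: marker particles for the M181 gate
    (z = box_z/2), the M308 G-loop constriction below it, the SF
    backbone-oxygen groups (T143O lower, Y146O upper) near the
    extracellular end, and I177 gate atoms on all four chains.  Mobile K+
    ions (tag "K") and water oxygens (tag "water-O") take Gaussian steps
    (sd ``step_sd`` nm per frame, plus ``drift`` nm/frame along +z),
    reflected at the cylinder wall and the box top/bottom.
    """
    rng = np.random.default_rng(seed)
    zc = box_z / 2.0
    rows = []
    # fixed scaffold: markers on each chain at a small ring radius
    ring = 0.35
    chain_xy = {"A": (ring, 0.0), "B": (0.0, ring),
                "C": (-ring, 0.0), "D": (0.0, -ring)}
    scaffold = []
    next_id = 0
    for tag, z in (("M181", zc), ("M308", zc - 2.0), ("M302", zc - 2.6),
                   ("I177", zc + 0.3),
                   ("T143O", zc + 2.0), ("Y146O", zc + 2.5)):
        for chain, (x, y) in chain_xy.items():
            scaffold.append((next_id, tag, chain, x, y, z))
            next_id += 1

    specs = [("K", n_ions), ("water-O", n_waters)]
    mobile_ids, mobile_tags = [], []
    pos = []
    for tag, n in specs:
        for _ in range(n):
            r = pore_radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            pos.append([r * np.cos(th), r * np.sin(th),
                        rng.uniform(0, box_z)])
            mobile_ids.append(next_id)
            mobile_tags.append(tag)
            next_id += 1
    pos = np.asarray(pos, float) if pos else np.empty((0, 3))

    for f in range(n_frames):
        for (pid, tag, chain, x, y, z) in scaffold:
            rows.append((f, pid, tag, chain, x, y, z))
        for j, (pid, tag) in enumerate(zip(mobile_ids, mobile_tags)):
            rows.append((f, pid, tag, "-", *pos[j]))
        if f < n_frames - 1 and len(pos):
            step = rng.normal(0.0, step_sd, size=pos.shape)
            step[:, 2] += drift
            pos = pos + step
            # reflect at box top/bottom in z
            pos[:, 2] = np.abs(pos[:, 2])
            over = pos[:, 2] > box_z
            pos[over, 2] = 2 * box_z - pos[over, 2]
            # reflect radially at the pore wall
            r = np.hypot(pos[:, 0], pos[:, 1])
            out = r > pore_radius
            if out.any():
                scale = (2 * pore_radius - r[out]) / r[out]
                pos[out, 0] *= scale
                pos[out, 1] *= scale

    df = pd.DataFrame(rows, columns=list(FRAME_COLUMNS))
    return TrajectoryFrames(df=df, frame_interval_ps=frame_interval_ps,
                            box=(2 * pore_radius, 2 * pore_radius, box_z),
                            label=label)
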