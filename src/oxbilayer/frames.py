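"""In-memory containers: particle tables, single frames, trajectories.

Coordinates are stored in nm; the z axis is the membrane normal by
convention.  Particle metadata is kept as flat numpy arrays so metric code
can vectorize over frames and residues.  Residues are stored contiguously
and template-ordered (the file readers validate this on load).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import TrajectoryError
from .topology import LipidTemplate, WATER_RESNAME


@dataclass
class Topology:
    """Per-particle metadata shared by every frame of a system."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    lipid_ids: np.ndarray  # shared by OX3A/OX3B pairs; -1 for water
    elements: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        arrays = (self.names, self.resnames, self.resids, self.lipid_ids,
                  self.elements, self.masses)
        n = len(self.names)
        if any(len(a) != n for a in arrays):
            raise TrajectoryError("topology arrays must have equal length")
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=np.int64)
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_particles(self) -> int:
        return len(self.names)

    @property
    def is_water(self) -> np.ndarray:
        return self.resnames == WATER_RESNAME

    @property
    def is_water_oxygen(self) -> np.ndarray:
        return self.is_water & (self.elements == "O")

    @property
    def is_phosphorus(self) -> np.ndarray:
        return self.elements == "P"

    def n_lipids(self) -> int:
        """Number of lipids, counting an OX3A/OX3B pair as one."""
        ids = self.lipid_ids[self.lipid_ids >= 0]
        return len(np.unique(ids))


def species_particle_indices(top: Topology, resname: str) -> np.ndarray:
    """Particle indices of every residue of ``resname``.

    Returns an integer array of shape (n_residues, n_particles_per_residue);
    relies on residues being contiguous and uniformly sized.
    """
    idx = np.flatnonzero(top.resnames == resname)
    if idx.size == 0:
        return np.empty((0, 0), dtype=np.int64)
    breaks = np.flatnonzero(np.diff(top.resids[idx]) != 0)
    groups = np.split(idx, breaks + 1)
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise TrajectoryError(
            f"residues of {resname} are not uniformly sized: {sorted(sizes)}")
    return np.vstack(groups)


def validate_against_template(top: Topology, resname: str,
                              template: LipidTemplate) -> np.ndarray:
    """Check residue layout against a template; return residue index matrix."""
    mat = species_particle_indices(top, resname)
    if mat.size and mat.shape[1] != template.n_particles:
        raise TrajectoryError(
            f"{resname} residues have {mat.shape[1]} particles; template "
            f"has {template.n_particles}")
    return mat


@dataclass
class Frame:
    """A single configuration: coordinates (nm) plus box vectors (nm)."""

    top: Topology
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.shape != (self.top.n_particles, 3):
            raise TrajectoryError("coords shape does not match topology")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise TrajectoryError("box must be three positive lengths (nm)")


@dataclass
class PackedFrame(Frame):
    """A packed initial configuration with per-lipid leaflet assignment."""

    leaflets: dict[int, str] = field(default_factory=dict)


@dataclass
class Trajectory:
    """Ordered frames over a fixed particle set.

    times are in ps and strictly increasing; boxes may fluctuate per frame
    (NPT-like), coordinates are (n_frames, n_particles, 3) in nm.
    """

    top: Topology
    times: np.ndarray
    boxes: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        t = len(self.times)
        if t == 0:
            raise TrajectoryError("trajectory has no frames")
        if np.any(np.diff(self.times) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if self.boxes.shape != (t, 3) or np.any(self.boxes <= 0):
            raise TrajectoryError("boxes must have shape (n_frames, 3), > 0")
        if self.coords.shape != (t, self.top.n_particles, 3):
            raise TrajectoryError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{t} frames x {self.top.n_particles} particles")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Frame:
        return Frame(self.top, self.coords[i], self.boxes[i])

    @classmethod
    def from_frame(cls, frame: Frame, time: float = 0.0) -> "Trajectory":
        return cls(frame.top, np.array([time]), frame.box[None, :],
                   frame.coords[None, :, :])


def default_equil_time(traj: Trajectory) -> float:
    """Midpoint of the recorded time span (first half = equilibration)."""
    return float((traj.times[0] + traj.times[-1]) / 2.0)


def frames_after_equilibration(traj: Trajectory,
                               equil_time: float | None) -> np.ndarray:
    """Boolean mask of production frames.

    An explicit ``equil_time`` keeps frames with time strictly greater than
    it; the default keeps the second half of the recorded span (inclusive of
    the midpoint, so a single-frame trajectory is fully used).
    """
    if equil_time is None:
        used = traj.times >= default_equil_time(traj)
    else:
        used = traj.times > equil_time
    if not used.any():
        raise TrajectoryError(
            f"no frames after equilibration time {equil_time} ps "
            f"(trajectory spans {traj.times[0]}..{traj.times[-1]} ps)")
    return used
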