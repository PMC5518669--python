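"""Shared fixtures: hand-built minimal trajectories with known structure."""

import numpy as np
import pytest

from oxbilayer.frames import Topology, Trajectory


def water_topology(n_mol: int) -> Topology:
    """Single-site waters (OW only, full molecule mass) for density tests."""
    return Topology(
        names=np.array(["OW"] * n_mol),
        resnames=np.array(["SOL"] * n_mol),
        resids=np.arange(1, n_mol + 1),
        lipid_ids=np.full(n_mol, -1),
        elements=np.array(["O"] * n_mol),
        masses=np.full(n_mol, 18.015),
    )


def p_plane_topology(n_p: int) -> Topology:
    """Bare phosphorus particles, one per residue."""
    return Topology(
        names=np.array(["P1"] * n_p),
        resnames=np.array(["PLN"] * n_p),
        resids=np.arange(1, n_p + 1),
        lipid_ids=np.arange(1, n_p + 1),
        elements=np.array(["P"] * n_p),
        masses=np.full(n_p, 30.974),
    )


def stack_topologies(*tops: Topology) -> Topology:
    resid_offset = 0
    lid_offset = 0
    parts = {k: [] for k in ("names", "resnames", "resids", "lipid_ids",
                             "elements", "masses")}
    for t in tops:
        parts["names"].append(t.names)
        parts["resnames"].append(t.resnames)
        parts["resids"].append(t.resids + resid_offset)
        lids = t.lipid_ids.copy()
        lids[lids >= 0] += lid_offset
        parts["lipid_ids"].append(lids)
        parts["elements"].append(t.elements)
        parts["masses"].append(t.masses)
        resid_offset += int(t.resids.max())
        if (t.lipid_ids >= 0).any():
            lid_offset += int(t.lipid_ids.max())
    return Topology(**{k: np.concatenate(v) for k, v in parts.items()})


def single_frame_traj(top: Topology, coords: np.ndarray,
                      box=(6.0, 6.0, 10.0), time: float = 0.0) -> Trajectory:
    return Trajectory(top, np.array([time]), np.array([box], dtype=float),
                      np.asarray(coords, dtype=float)[None])


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same stream regardless of which
    # other tests ran before it
    return np.random.default_rng(20260923)
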