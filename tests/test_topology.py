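"""Templates against molecular-formula oracles; deuterium geometry against
direct trigonometric construction."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxbilayer.exceptions import UnknownSpeciesError
from oxbilayer.topology import (DeuteriumGeometry, build_ox3_pair,
                                build_template, ideal_zigzag,
                                reconstruct_deuteriums, template_registry)

# independent oracle: molecular formulas (C, H, N, O, P) of each species
FORMULAS = {
    "POPC": (42, 82, 1, 8, 1),
    "CHOL": (27, 46, 0, 1, 0),
    "OX1": (42, 82, 1, 10, 1),
    "OX2": (33, 64, 1, 9, 1),
    "OX3A": (33, 64, 1, 9, 1),
    "OX3B": (9, 18, 0, 1, 0),
}
_W = dict(C=12.011, H=1.008, N=14.007, O=15.999, P=30.974)


def formula_mass(f):
    c, h, n, o, p = f
    return c * _W["C"] + h * _W["H"] + n * _W["N"] + o * _W["O"] + p * _W["P"]


@pytest.mark.parametrize("species,formula", FORMULAS.items())
def test_template_matches_molecular_formula(species, formula):
    """Implied atom counts and total mass agree with the all-atom formula."""
    t = build_template(species)
    assert t.implied_atom_count == sum(formula)
    assert t.total_mass == pytest.approx(formula_mass(formula), abs=0.1)
    # element bookkeeping: heavy atoms + retained polar hydrogens
    c, h, n, o, p = formula
    heavy = c + n + o + p
    polar_h = sum(1 for part in t.particles if part.element == "H")
    assert t.n_particles == heavy + polar_h
    assert sum(part.n_merged_h for part in t.particles) == h - polar_h


def test_popc_united_atom_reduction():
    """POPC reduces 134 atoms to exactly 52 united-atom particles."""
    t = build_template("POPC")
    assert t.n_particles == 52
    assert t.implied_atom_count == 134


def test_cholesterol_single_hydroxyl():
    t = build_template("CHOL")
    assert sum(1 for p in t.particles if p.element == "H") == 1
    assert t.polar_marker_indices == ()
    assert t.phosphate_index is None


def test_oxidation_markers():
    assert len(build_template("OX1").polar_marker_indices) == 2  # -O-O-H
    for sp in ("OX2", "OX3A", "OX3B"):
        assert len(build_template(sp).polar_marker_indices) == 1  # aldehyde O


def test_ox3_requested_as_pair():
    with pytest.raises(UnknownSpeciesError, match="two-fragment"):
        build_template("OX3")
    a, b = build_ox3_pair()
    assert (a.species, b.species) == ("OX3A", "OX3B")


def test_unknown_species_rejected():
    with pytest.raises(UnknownSpeciesError, match="unknown species"):
        build_template("DOPC")


def test_sn1_chain_bonded_in_order():
    for sp in ("POPC", "OX1", "OX2", "OX3A"):
        t = build_template(sp)
        bonds = {frozenset(b) for b in t.bonds}
        assert len(t.sn1_chain) == 16  # palmitoyl C1..C16
        for a, b in zip(t.sn1_chain, t.sn1_chain[1:]):
            assert frozenset((a, b)) in bonds


def test_template_table_serialization():
    t = build_template("POPC")
    lines = t.to_table().strip().splitlines()
    assert len(lines) == 2 + t.n_particles
    idx, name, el, nh, mass = lines[2].split()
    assert (int(idx), el) == (0, "C")


def _oracle_zigzag(n):
    """Independent all-trans chain: explicit trig, no package geometry."""
    gamma = math.radians((180.0 - 109.471) / 2.0)
    bond = 0.153
    pts = np.zeros((n, 3))
    for k in range(n):
        pts[k] = (bond * math.sin(gamma) * (k % 2), 0.0,
                  -k * bond * math.cos(gamma))
    return pts


def test_deuteriums_perpendicular_to_vertical_chain():
    """On an ideal z-aligned zig-zag every C-D direction has zero z."""
    t = build_template("POPC")
    coords = np.zeros((t.n_particles, 3))
    coords[list(t.sn1_chain)] = _oracle_zigzag(len(t.sn1_chain))
    out = reconstruct_deuteriums(coords, t)
    assert len(out) == len(t.sn1_chain) - 2  # CD2 carbons only
    for _, d1, d2 in out:
        assert abs(d1[2]) < 1e-6 and abs(d2[2]) < 1e-6
        assert np.linalg.norm(d1) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(d2) == pytest.approx(1.0, abs=1e-9)


def test_deuterium_pair_angle_and_neighbour_symmetry(rng):
    """D1-C-D2 equals the requested angle; both D make equal angles with
    the two heavy neighbours -- checked by direct dot products on random
    distorted chains."""
    t = build_template("POPC")
    geom = DeuteriumGeometry()
    coords = np.zeros((t.n_particles, 3))
    chain = list(t.sn1_chain)
    coords[chain] = _oracle_zigzag(len(chain)) + rng.normal(0, 0.02,
                                                            (len(chain), 3))
    for carbon, d1, d2 in reconstruct_deuteriums(coords, t):
        ang = math.degrees(math.acos(np.clip(d1 @ d2, -1, 1)))
        assert ang == pytest.approx(geom.hdh_angle, abs=1e-6)
        k = chain.index(carbon)
        a = coords[chain[k - 1]] - coords[carbon]
        b = coords[chain[k + 1]] - coords[carbon]
        a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
        for d in (d1, d2):
            assert d @ a == pytest.approx(d @ b, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(angles=st.tuples(*(st.floats(0, 2 * math.pi) for _ in range(3))))
def test_deuterium_rotation_equivariance(angles):
    """rotate-then-reconstruct equals reconstruct-then-rotate."""
    ax, ay, az = angles
    rx = np.array([[1, 0, 0], [0, math.cos(ax), -math.sin(ax)],
                   [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)], [0, 1, 0],
                   [-math.sin(ay), 0, math.cos(ay)]])
    rz = np.array([[math.cos(az), -math.sin(az), 0],
                   [math.sin(az), math.cos(az), 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    t = build_template("POPC")
    coords = np.zeros((t.n_particles, 3))
    coords[list(t.sn1_chain)] = _oracle_zigzag(len(t.sn1_chain))
    base = reconstruct_deuteriums(coords, t)
    rotated = reconstruct_deuteriums(coords @ rot.T, t)
    for (c0, d1a, d2a), (c1, d1b, d2b) in zip(base, rotated):
        assert c0 == c1
        assert np.allclose(rot @ d1a, d1b, atol=1e-10)
        assert np.allclose(rot @ d2a, d2b, atol=1e-10)


def test_collinear_carbon_skipped_with_warning():
    t = build_template("POPC")
    coords = np.zeros((t.n_particles, 3))
    pts = _oracle_zigzag(len(t.sn1_chain))
    pts[:3, 0] = 0.0  # first three chain carbons now exactly collinear in z
    pts[:3, 2] = -0.153 * np.arange(3)
    coords[list(t.sn1_chain)] = pts
    with pytest.warns(UserWarning, match="collinear"):
        out = reconstruct_deuteriums(coords, t)
    carbons = [c for c, _, _ in out]
    assert t.sn1_chain[1] not in carbons  # the degenerate carbon
    assert len(out) < len(t.sn1_chain) - 2


def test_registry_and_zigzag_helper():
    reg = template_registry()
    assert set(reg) == {"POPC", "CHOL", "OX1", "OX2", "OX3A", "OX3B"}
    zz = ideal_zigzag(8)
    steps = np.linalg.norm(np.diff(zz, axis=0), axis=1)
    assert np.allclose(steps, 0.153, atol=1e-12)
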