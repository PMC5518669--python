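"""United-atom lipid templates and deuterium reconstruction.

The five membrane species handled here are POPC, cholesterol (CHOL) and three
peroxidation products of POPC's oleoyl (sn-2) chain:

* ``OX1`` -- the hydroperoxide: an -OOH group on the sn-2 C9 with the double
  bond shifted to C10=C11.
* ``OX2`` -- oxidative chain cleavage at the double bond, keeping only the
  phospholipid fragment whose sn-2 chain ends in an aldehyde (9-oxononanoyl).
* ``OX3`` -- the same cleavage keeping *both* fragments: the phospholipid
  aldehyde (``OX3A``, identical connectivity to OX2) and the short-chain
  aldehyde (``OX3B``, a nonanal-type C9 aldehyde).  The two fragments are
  bookkept as ONE lipid everywhere (area per lipid, compositions).

In the united-atom representation every aliphatic carbon absorbs its bonded
hydrogens (CH, CH2, CH3 become single particles); polar hydrogens (hydroxyl,
hydroperoxide, water) remain explicit.  A POPC molecule with 134 atoms reduces
to 52 particles.

Because deuteriums are not explicit particles, the deuterium order parameter
analysis reconstructs the two C-D directions of every CD2 carbon of the sn-1
(palmitoyl) chain from the positions of its two heavy neighbours, assuming
ideal sp3 (tetrahedral) geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .exceptions import UnknownSpeciesError

ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}

#: Residue names of all known species, in canonical order.
SPECIES = ("POPC", "CHOL", "OX1", "OX2", "OX3A", "OX3B")

#: Residue name used for water (three-site: OW, HW1, HW2).
WATER_RESNAME = "SOL"
WATER_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]  # 18.015 amu


@dataclass(frozen=True)
class Particle:
    """One united-atom particle: a heavy atom plus its merged hydrogens."""

    name: str
    element: str
    n_merged_h: int
    mass: float

    def __post_init__(self):
        if self.element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {self.element!r}")
        if self.n_merged_h not in (0, 1, 2, 3):
            raise ValueError(f"n_merged_h must be 0..3, got {self.n_merged_h}")
        if self.element == "H" and self.n_merged_h != 0:
            raise ValueError("a polar hydrogen cannot merge further hydrogens")
        if self.mass <= 0:
            raise ValueError("particle mass must be positive")


@dataclass(frozen=True)
class DeuteriumGeometry:
    """Ideal sp3 geometry used to rebuild C-D bonds on united-atom carbons.

    Only the direction of the C-D bond enters the order parameter, so
    ``bond_length`` has no downstream effect; it is kept for completeness.
    """

    bond_length: float = 0.1  # nm
    hdh_angle: float = 109.471  # degrees, ideal tetrahedral D-C-D angle

    def __post_init__(self):
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if not 0.0 < self.hdh_angle < 180.0:
            raise ValueError("hdh_angle must lie strictly between 0 and 180")


@dataclass(frozen=True)
class LipidTemplate:
    """Topology of one united-atom species.

    ``sn1_chain`` lists the palmitoyl carbons in bonded order starting at the
    ester carbonyl carbon and ending at the terminal methyl; the order
    parameter analysis rebuilds deuteriums on its interior carbons only.
    """

    species: str
    particles: tuple[Particle, ...]
    bonds: tuple[tuple[int, int], ...]
    sn1_chain: tuple[int, ...] = ()
    phosphate_index: int | None = None
    polar_marker_indices: tuple[int, ...] = ()

    def __post_init__(self):
        n = len(self.particles)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for {n} particles")
        for idx in (*self.sn1_chain, *self.polar_marker_indices):
            if not 0 <= idx < n:
                raise ValueError(f"particle index {idx} out of range")
        if self.phosphate_index is not None:
            if not 0 <= self.phosphate_index < n:
                raise ValueError("phosphate_index out of range")
            if self.particles[self.phosphate_index].element != "P":
                raise ValueError("phosphate_index does not point at a P particle")
        bondset = {frozenset(b) for b in self.bonds}
        for a, b in zip(self.sn1_chain[:-1], self.sn1_chain[1:]):
            if frozenset((a, b)) not in bondset:
                raise ValueError("sn1_chain indices must be pairwise bonded in order")

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def implied_atom_count(self) -> int:
        """Number of atoms in the underlying all-atom molecule."""
        return sum(1 + p.n_merged_h for p in self.particles)

    @property
    def total_mass(self) -> float:
        """Molecular mass in amu (equals the all-atom molecular mass)."""
        return float(sum(p.mass for p in self.particles))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.particles)

    def heavy_neighbours(self, index: int) -> tuple[int, ...]:
        """Indices of non-hydrogen particles bonded to ``index``."""
        out = []
        for i, j in self.bonds:
            if i == index and self.particles[j].element != "H":
                out.append(j)
            elif j == index and self.particles[i].element != "H":
                out.append(i)
        return tuple(sorted(out))

    def to_table(self) -> str:
        """Serialize the particle list as a plain-text table.

        Columns: index, name, element, n_merged_h, mass (amu).
        """
        lines = [f"# species {self.species}",
                 "# index name element n_merged_h mass_amu"]
        for i, p in enumerate(self.particles):
            lines.append(f"{i:5d} {p.name:>5s} {p.element:>2s} "
                         f"{p.n_merged_h:1d} {p.mass:8.3f}")
        return "\n".join(lines) + "\n"


def _make_particles(rows: list[tuple[str, int]]) -> tuple[Particle, ...]:
    """Rows of (element, n_merged_h); names are element + 1-based serial."""
    out = []
    for i, (el, nh) in enumerate(rows):
        mass = ATOMIC_MASS[el] + nh * ATOMIC_MASS["H"]
        out.append(Particle(name=f"{el}{i + 1}", element=el, n_merged_h=nh, mass=mass))
    return tuple(out)


def _chain_bonds(start: int, stop: int) -> list[tuple[int, int]]:
    return [(i, i + 1) for i in range(start, stop)]


# ---------------------------------------------------------------------------
# species definitions
#
# Particle ordering convention (stable, documented):
#   choline methyls (3), N, N-CH2, O-CH2 | phosphate O,P,O,O,O | glycerol C3
#   | sn-1 ester O, carbonyl C, carbonyl O, chain C2..Cn
#   | sn-2 ester O, carbonyl C, carbonyl O, chain C2..Cn [+ oxidation extras]
# ---------------------------------------------------------------------------

def _popc_like_rows(sn2_tail: list[tuple[str, int]]) -> list[tuple[str, int]]:
    head = [("C", 3), ("C", 3), ("C", 3), ("N", 0), ("C", 2), ("C", 2),
            ("O", 0), ("P", 0), ("O", 0), ("O", 0), ("O", 0),
            ("C", 2), ("C", 1), ("C", 2)]
    sn1 = [("O", 0), ("C", 0), ("O", 0)] + [("C", 2)] * 14 + [("C", 3)]
    sn2_head = [("O", 0), ("C", 0), ("O", 0)]
    return head + sn1 + sn2_head + sn2_tail


def _popc_like_bonds(n_sn2_tail: int) -> list[tuple[int, int]]:
    bonds = [(0, 3), (1, 3), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7),
             (7, 8), (7, 9), (7, 10), (10, 11), (11, 12), (12, 13),
             # sn-1 ester off glycerol C3 (index 13), sn-2 ester off C2 (12)
             (13, 14), (14, 15), (15, 16), (15, 17),
             (12, 32), (32, 33), (33, 34)]
    bonds += _chain_bonds(17, 31)          # sn-1 chain C2..C16
    if n_sn2_tail:
        bonds.append((33, 35))             # sn-2 carbonyl to C2
        bonds += _chain_bonds(35, 35 + n_sn2_tail - 1)
    return bonds


_SN1_CHAIN = (15,) + tuple(range(17, 32))  # carbonyl C1 then C2..C16

_OLEOYL_TAIL = ([("C", 2)] * 7 + [("C", 1), ("C", 1)] + [("C", 2)] * 7
                + [("C", 3)])  # C2..C8, C9=C10, C11..C17, C18

_CHOL_NH = [2, 2, 1, 2, 0, 1, 2, 1, 1, 0, 2, 2, 0, 1, 2, 2, 1,
            3, 3, 1, 3, 2, 2, 2, 1, 3, 3]  # C1..C27
_CHOL_BONDS = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7),
               (7, 8), (8, 9), (9, 0), (4, 9), (7, 13), (8, 10), (10, 11),
               (11, 12), (12, 13), (13, 14), (14, 15), (15, 16), (12, 16),
               (9, 18), (12, 17), (16, 19), (19, 20), (19, 21), (21, 22),
               (22, 23), (23, 24), (24, 25), (24, 26), (2, 27), (27, 28)]


@lru_cache(maxsize=None)
def build_template(species: str) -> LipidTemplate:
    """Build the united-atom template for one species.

    Parameters
    ----------
    species : str
        One of ``POPC, CHOL, OX1, OX2, OX3A, OX3B`` (case-insensitive).
        The two-fragment product OX3 must be requested as its pair of
        fragments; see :func:`build_ox3_pair`.

    Raises
    ------
    UnknownSpeciesError
        For any other label, including the bare ``"OX3"``.
    """
    label = str(species).upper()
    if label == "OX3":
        raise UnknownSpeciesError(
            "OX3 is a two-fragment species: request 'OX3A' and 'OX3B' "
            "separately (or use build_ox3_pair()); the pair counts as one lipid")
    if label not in SPECIES:
        raise UnknownSpeciesError(
            f"unknown species {species!r}; expected one of {', '.join(SPECIES)}")

    if label == "POPC":
        rows = _popc_like_rows(_OLEOYL_TAIL)
        return LipidTemplate("POPC", _make_particles(rows),
                             tuple(_popc_like_bonds(len(_OLEOYL_TAIL))),
                             sn1_chain=_SN1_CHAIN, phosphate_index=7)

    if label == "OX1":
        tail = list(_OLEOYL_TAIL)
        tail[9] = ("C", 1)  # oleoyl C11 loses one H: C9-OOH, C10=C11 shift
        rows = _popc_like_rows(tail) + [("O", 0), ("O", 0), ("H", 0)]
        bonds = _popc_like_bonds(len(tail)) + [(42, 52), (52, 53), (53, 54)]
        return LipidTemplate("OX1", _make_particles(rows), tuple(bonds),
                             sn1_chain=_SN1_CHAIN, phosphate_index=7,
                             polar_marker_indices=(52, 53))

    if label in ("OX2", "OX3A"):
        # sn-2 = 9-oxononanoyl: C2..C8 methylenes, C9 aldehyde CH, =O
        tail = [("C", 2)] * 7 + [("C", 1)]
        rows = _popc_like_rows(tail) + [("O", 0)]
        bonds = _popc_like_bonds(len(tail)) + [(42, 43)]
        return LipidTemplate(label, _make_particles(rows), tuple(bonds),
                             sn1_chain=_SN1_CHAIN, phosphate_index=7,
                             polar_marker_indices=(43,))

    if label == "OX3B":
        # nonanal-type short-chain aldehyde: CHO, 7 CH2, CH3
        rows = [("C", 1), ("O", 0)] + [("C", 2)] * 7 + [("C", 3)]
        bonds = [(0, 1), (0, 2)] + _chain_bonds(2, 9)
        return LipidTemplate("OX3B", _make_particles(rows), tuple(bonds),
                             polar_marker_indices=(1,))

    # CHOL
    rows = [("C", nh) for nh in _CHOL_NH] + [("O", 0), ("H", 0)]
    return LipidTemplate("CHOL", _make_particles(rows), tuple(_CHOL_BONDS))


def build_ox3_pair() -> tuple[LipidTemplate, LipidTemplate]:
    """The two OX3 fragments; together they count as one lipid."""
    return build_template("OX3A"), build_template("OX3B")


def template_registry() -> dict[str, LipidTemplate]:
    """All templates keyed by residue name."""
    return {s: build_template(s) for s in SPECIES}


# ---------------------------------------------------------------------------
# reference conformations (schematic, head up / tail down, P-anchor at origin)
# ---------------------------------------------------------------------------

_ZZ_BOND = 0.153  # nm C-C
_ZZ_GAMMA = np.radians((180.0 - 109.471) / 2.0)  # bond-to-axis half angle
ZIGZAG_DZ = _ZZ_BOND * np.cos(_ZZ_GAMMA)
ZIGZAG_AMP = _ZZ_BOND * np.sin(_ZZ_GAMMA)


def ideal_zigzag(n: int, origin=(0.0, 0.0, 0.0), axis: str = "-z") -> np.ndarray:
    """Positions of an ideal all-trans (tetrahedral) zig-zag chain.

    The chain axis runs along ``axis``; the zig-zag lies in the plane spanned
    by that axis and x (or z for horizontal chains).
    """
    origin = np.asarray(origin, dtype=float)
    k = np.arange(n)
    amp = ZIGZAG_AMP * (k % 2)
    pos = np.zeros((n, 3))
    if axis == "-z":
        pos[:, 0] = amp
        pos[:, 2] = -k * ZIGZAG_DZ
    elif axis == "+x":
        pos[:, 2] = amp
        pos[:, 0] = k * ZIGZAG_DZ
    else:  # pragma: no cover - internal use only
        raise ValueError(f"unsupported axis {axis!r}")
    return pos + origin


def _popc_like_coords(template: LipidTemplate) -> np.ndarray:
    """Schematic conformation: P at the origin, choline above, tails below.

    The sn-1 chain (carbonyl through terminal methyl) sits on an exact ideal
    zig-zag along -z so that reconstructed C-D bonds are exactly perpendicular
    to the chain axis; everything else is a compact, chemically plausible
    arrangement sufficient for packing and density work.
    """
    n = template.n_particles
    xyz = np.zeros((n, 3))
    # choline
    xyz[3] = (0.00, 0.00, 0.58)  # N
    xyz[0] = (0.14, 0.00, 0.66)
    xyz[1] = (-0.07, 0.12, 0.66)
    xyz[2] = (-0.07, -0.12, 0.66)
    xyz[4] = (0.05, 0.00, 0.44)
    xyz[5] = (0.00, 0.00, 0.30)
    # phosphate
    xyz[6] = (0.00, 0.00, 0.15)
    xyz[7] = (0.00, 0.00, 0.00)  # P anchor
    xyz[8] = (0.12, 0.06, 0.02)
    xyz[9] = (-0.12, 0.06, 0.02)
    xyz[10] = (0.00, 0.00, -0.15)
    # glycerol
    xyz[11] = (0.00, 0.00, -0.30)
    xyz[12] = (0.05, 0.08, -0.42)
    xyz[13] = (0.00, 0.16, -0.52)
    # sn-1: ester O then ideal zig-zag from the carbonyl carbon
    xyz[14] = (0.00, 0.10, -0.58)
    chain = ideal_zigzag(len(_SN1_CHAIN), origin=(-0.04, 0.0, -0.66))
    for pos, idx in zip(chain, _SN1_CHAIN):
        xyz[idx] = pos
    xyz[16] = xyz[15] + (0.13, -0.08, 0.03)  # sn-1 carbonyl O
    # sn-2 at a lateral offset
    xyz[32] = (0.00, 0.28, -0.45)
    xyz[33] = (0.00, 0.28, -0.56)
    xyz[34] = (0.13, 0.35, -0.53)
    n_tail = sum(1 for i in range(35, n)
                 if template.particles[i].element == "C" and i >= 35)
    tail = ideal_zigzag(n_tail + 1, origin=(-0.04, 0.28, -0.56))[1:]
    ti = 0
    for i in range(35, n):
        if template.particles[i].element == "C":
            xyz[i] = tail[ti]
            ti += 1
    # oxidation extras hang off the last-touched chain carbon region
    if template.species == "OX1":
        c9 = xyz[42]
        xyz[52] = c9 + (0.13, -0.10, 0.02)
        xyz[53] = c9 + (0.24, -0.17, 0.08)
        xyz[54] = c9 + (0.30, -0.23, 0.13)
    elif template.species in ("OX2", "OX3A"):
        xyz[43] = xyz[42] + (0.12, -0.08, -0.04)
    return xyz


def _chol_coords() -> np.ndarray:
    """Compact schematic cholesterol: hydroxyl at top, ring slab, short tail."""
    xyz = np.zeros((29, 3))
    xyz[27] = (0.00, 0.00, 0.05)   # O
    xyz[28] = (0.00, 0.00, 0.15)   # polar H
    for i in range(17):            # ring carbons C1..C17
        xyz[i] = (0.12 * (i % 2), 0.04 * ((i // 2) % 2), -0.05 - 0.082 * i)
    xyz[17] = xyz[12] + (-0.11, 0.10, 0.00)  # C18 methyl
    xyz[18] = xyz[9] + (-0.11, 0.10, 0.00)   # C19 methyl
    xyz[19] = xyz[16] + (0.06, 0.00, -0.12)  # C20
    xyz[20] = xyz[19] + (0.12, 0.09, 0.00)   # C21 methyl
    tail = ideal_zigzag(4, origin=xyz[19] + (0.0, 0.0, -0.125))
    xyz[21:25] = tail                         # C22..C25
    xyz[25] = xyz[24] + (0.10, 0.08, -0.06)
    xyz[26] = xyz[24] + (-0.10, 0.08, -0.06)
    return xyz


def reference_conformation(template: LipidTemplate) -> np.ndarray:
    """Idealized single-lipid coordinates (nm) in the template's own frame.

    Head group toward +z, tails toward -z; the anchor particle (phosphate,
    hydroxyl O for cholesterol, C1 for OX3B) sits at the origin.
    """
    if template.species in ("POPC", "OX1", "OX2", "OX3A"):
        return _popc_like_coords(template)
    if template.species == "CHOL":
        return _chol_coords()
    if template.species == "OX3B":
        # vertical, tail down: small lateral footprint eases core packing
        return ideal_zigzag(10, axis="-z")
    raise UnknownSpeciesError(template.species)  # pragma: no cover


def anchor_index(template: LipidTemplate) -> int:
    """Particle used to pin the lipid to its leaflet plane."""
    if template.phosphate_index is not None:
        return template.phosphate_index
    if template.species == "CHOL":
        return 27  # hydroxyl oxygen
    return 0


# ---------------------------------------------------------------------------
# deuterium reconstruction
# ---------------------------------------------------------------------------

_COLLINEAR_TOL = 1e-8


def cd_unit_vectors(chain_pos: np.ndarray,
                    geometry: DeuteriumGeometry = DeuteriumGeometry()
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized C-D direction reconstruction for bonded-in-order chains.

    Parameters
    ----------
    chain_pos : ndarray, shape (..., m, 3)
        Coordinates of m >= 3 chain carbons in bonded order.
    geometry : DeuteriumGeometry
        D-C-D angle (the bond length is irrelevant to directions).

    Returns
    -------
    d : ndarray, shape (..., m - 2, 2, 3)
        Unit C-D vectors for each interior carbon (NaN where degenerate).
    valid : ndarray of bool, shape (..., m - 2)
        False where the two heavy neighbours are collinear with the carbon.

    Notes
    -----
    With unit vectors a, b from the carbon to its two heavy neighbours,
    u = -(a + b)/|a + b| and v = (a x b)/|a x b|; the two C-D directions are
    u cos(half) +/- v sin(half) with half = hdh_angle / 2.  Both make equal
    angles with a and b, and their mutual angle is exactly hdh_angle.
    """
    chain_pos = np.asarray(chain_pos, dtype=float)
    a = chain_pos[..., :-2, :] - chain_pos[..., 1:-1, :]
    b = chain_pos[..., 2:, :] - chain_pos[..., 1:-1, :]
    a = a / np.linalg.norm(a, axis=-1, keepdims=True)
    b = b / np.linalg.norm(b, axis=-1, keepdims=True)
    s = -(a + b)
    v = np.cross(a, b)
    sn = np.linalg.norm(s, axis=-1, keepdims=True)
    vn = np.linalg.norm(v, axis=-1, keepdims=True)
    valid = (vn[..., 0] > _COLLINEAR_TOL) & (sn[..., 0] > _COLLINEAR_TOL)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = s / sn
        v = v / vn
    half = np.radians(geometry.hdh_angle) / 2.0
    d1 = u * np.cos(half) + v * np.sin(half)
    d2 = u * np.cos(half) - v * np.sin(half)
    d = np.stack([d1, d2], axis=-2)
    d[~valid] = np.nan
    return d, valid


def reconstruct_deuteriums(coords: np.ndarray, template: LipidTemplate,
                           geometry: DeuteriumGeometry = DeuteriumGeometry()
                           ) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Rebuild the two C-D unit vectors for every interior sn-1 carbon.

    Parameters
    ----------
    coords : ndarray, shape (n_particles, 3)
        Coordinates (nm) of the whole lipid, template-ordered.
    template : LipidTemplate
        Must carry a non-trivial ``sn1_chain``.
    geometry : DeuteriumGeometry

    Returns
    -------
    list of (carbon_index, d1, d2)
        One entry per CD2 carbon (chain interior).  Carbons whose neighbours
        are collinear are skipped with a warning.
    """
    chain = template.sn1_chain
    if len(chain) < 3:
        return []
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (template.n_particles, 3):
        raise ValueError(
            f"coords shape {coords.shape} does not match template "
            f"({template.n_particles} particles)")
    d, valid = cd_unit_vectors(coords[list(chain)], geometry)
    out = []
    for k, carbon in enumerate(chain[1:-1]):
        if not valid[k]:
            warnings.warn(
                f"collinear neighbours at {template.species} particle "
                f"{template.particles[carbon].name}; carbon skipped",
                stacklevel=2)
            continue
        out.append((carbon, d[k, 0], d[k, 1]))
    return out
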