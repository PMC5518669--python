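"""Composition bookkeeping and initial-configuration packing.

Model systems contain 72 lipids (POPC, cholesterol and optionally one
peroxidation product) plus 4000 waters in a box of about 5.5 x 5.5 x 11 nm.
Oxidized species replace POPC in the non-cholesterol pool; for OX3 each
replacement inserts BOTH fragments (OX3A + OX3B) which together count as one
lipid.  Packing places lipids at random lateral positions and orientations in
two leaflets, rejecting placements that bring particles of different lipids
closer than a minimum distance (default 2 A), with periodic minimum-image
distances.  Water fills the two slabs outside the lipid region.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CompositionError, PackingError
from .frames import PackedFrame, Topology
from .topology import (ATOMIC_MASS, WATER_RESNAME, anchor_index,
                       build_template, reference_conformation)

DEFAULT_BOX = (5.5, 5.5, 11.0)  # nm
OX_SPECIES = ("OX1", "OX2", "OX3")


def _round_half_even(x: float) -> int:
    # float(np.round) is banker's rounding, matching the documented rule
    return int(np.round(x))


@dataclass
class SystemComposition:
    """Counts of each lipid species plus water and box dimensions.

    ``n_ox`` counts OX3 fragment PAIRS: each pair is one lipid, two residues.
    Requested fractions (if built via :func:`make_composition`) are retained
    so realized integer fractions can be reported alongside them.
    """

    n_popc: int
    n_chol: int
    n_ox: int
    ox_species: str | None = None
    n_lipids_total: int = 72
    n_water: int = 4000
    box: tuple[float, float, float] = DEFAULT_BOX
    requested_chol_fraction: float | None = None
    requested_ox_fraction: float | None = None

    def __post_init__(self):
        counts = (self.n_popc, self.n_chol, self.n_ox, self.n_water)
        if any(c < 0 for c in counts):
            raise CompositionError("species and water counts must be >= 0")
        if self.n_popc + self.n_chol + self.n_ox != self.n_lipids_total:
            raise CompositionError(
                f"species counts {self.n_popc}+{self.n_chol}+{self.n_ox} "
                f"do not sum to n_lipids_total={self.n_lipids_total}")
        if self.n_ox > 0:
            if self.ox_species not in OX_SPECIES:
                raise CompositionError(
                    f"ox_species must be one of {OX_SPECIES} when n_ox > 0")
        else:
            self.ox_species = None
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise CompositionError("box must be three positive lengths (nm)")
        self.box = tuple(float(b) for b in self.box)

    @property
    def realized_chol_fraction(self) -> float:
        return self.n_chol / self.n_lipids_total if self.n_lipids_total else 0.0

    @property
    def realized_ox_fraction(self) -> float:
        pool = self.n_lipids_total - self.n_chol
        return self.n_ox / pool if pool else 0.0

    def counts_by_species(self) -> dict[str, int]:
        """Lipid counts keyed by residue name (OX3 expands to its fragments)."""
        out: dict[str, int] = {}
        if self.n_popc:
            out["POPC"] = self.n_popc
        if self.n_chol:
            out["CHOL"] = self.n_chol
        if self.n_ox:
            if self.ox_species == "OX3":
                out["OX3A"] = self.n_ox
                out["OX3B"] = self.n_ox
            else:
                out[self.ox_species] = self.n_ox
        return out

    def n_residues_lipid(self) -> int:
        return sum(self.counts_by_species().values())

    @property
    def n_per_leaflet(self) -> int:
        """Lipids in the fuller leaflet (pairs count once)."""
        return self.n_lipids_total - self.n_lipids_total // 2

    def per_leaflet(self) -> tuple[dict[str, int], dict[str, int]]:
        """Split each species between leaflets; upper takes the odd one."""
        upper: dict[str, int] = {}
        lower: dict[str, int] = {}
        pair = {"POPC": self.n_popc, "CHOL": self.n_chol}
        if self.n_ox:
            pair[self.ox_species] = self.n_ox  # OX3 counted as pairs here
        for sp, n in pair.items():
            upper[sp] = n - n // 2
            lower[sp] = n // 2
        return upper, lower


def make_composition(n_lipids: int = 72, chol_fraction: float = 0.0,
                     ox_fraction: float = 0.0, ox_species: str | None = None,
                     n_water: int = 4000,
                     box: tuple[float, float, float] = DEFAULT_BOX
                     ) -> SystemComposition:
    """Turn target fractions into integer species counts.

    The cholesterol fraction applies to all lipids; the oxidation fraction
    applies to the non-cholesterol (POPC) pool, mirroring the construction in
    which POPC molecules are replaced by an oxidation product.  Counts are
    rounded half-to-even and POPC absorbs the remainder, so realized
    fractions (reported on the result) may differ slightly from requests.
    """
    if n_lipids < 0:
        raise CompositionError("n_lipids must be >= 0")
    for name, frac in (("chol_fraction", chol_fraction),
                       ("ox_fraction", ox_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise CompositionError(f"{name}={frac} outside [0, 1]")
    if ox_species is not None and str(ox_species).lower() in ("", "none"):
        ox_species = None
    if ox_species is not None:
        ox_species = str(ox_species).upper()
        if ox_species not in OX_SPECIES:
            raise CompositionError(
                f"ox_species must be one of {OX_SPECIES}, got {ox_species!r}")
    if ox_fraction > 0 and ox_species is None:
        raise CompositionError("ox_fraction > 0 requires an ox_species")

    n_chol = _round_half_even(chol_fraction * n_lipids)
    pool = n_lipids - n_chol
    n_ox = _round_half_even(ox_fraction * pool) if ox_species else 0
    n_popc = n_lipids - n_chol - n_ox
    if n_popc < 0:
        raise CompositionError("requested fractions leave a negative POPC count")
    return SystemComposition(
        n_popc=n_popc, n_chol=n_chol, n_ox=n_ox,
        ox_species=ox_species if n_ox else None,
        n_lipids_total=n_lipids, n_water=n_water, box=box,
        requested_chol_fraction=chol_fraction,
        requested_ox_fraction=ox_fraction)


def enumerate_study_grid(ox_species: list[str],
                         ox_fractions: list[float],
                         chol_fractions: list[float],
                         n_lipids: int = 72,
                         n_water: int = 4000,
                         box: tuple[float, float, float] = DEFAULT_BOX
                         ) -> list[SystemComposition]:
    """All unique compositions on a species x oxidation x cholesterol grid.

    Grid points whose integer counts coincide are deduplicated; in particular
    0% oxidation collapses across oxidation species.
    """
    seen = set()
    out = []
    for chol, frac, sp in itertools.product(chol_fractions, ox_fractions,
                                            ox_species):
        comp = make_composition(n_lipids, chol, frac, sp,
                                n_water=n_water, box=box)
        key = (comp.n_popc, comp.n_chol, comp.n_ox, comp.ox_species)
        if key not in seen:
            seen.add(key)
            out.append(comp)
    return out


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


class _CellGrid:
    """Uniform cell list for neighbour queries under full 3D periodicity."""

    def __init__(self, box: np.ndarray, cutoff: float):
        self.box = box
        self.n = np.maximum(1, np.floor(box / cutoff).astype(int))
        self.cells: dict[tuple[int, int, int], list[int]] = {}
        self.coords: list[np.ndarray] = []
        self.owner: list[int] = []

    def _cell_of(self, p: np.ndarray) -> tuple[int, int, int]:
        c = np.floor(p / self.box * self.n).astype(int) % self.n
        return tuple(c)

    def add(self, pts: np.ndarray, owner: int) -> None:
        for p in pts:
            idx = len(self.coords)
            self.coords.append(p)
            self.owner.append(owner)
            self.cells.setdefault(self._cell_of(p), []).append(idx)

    def clashes(self, pts: np.ndarray, owner: int, cutoff: float) -> bool:
        cut2 = cutoff * cutoff
        for p in pts:
            cx, cy, cz = self._cell_of(p)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        key = ((cx + dx) % self.n[0], (cy + dy) % self.n[1],
                               (cz + dz) % self.n[2])
                        for idx in self.cells.get(key, ()):
                            if self.owner[idx] == owner:
                                continue
                            d = _min_image(p - self.coords[idx], self.box)
                            if d @ d < cut2:
                                return True
        return False


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: head down


def _random_water_orientation(rng: np.random.Generator) -> np.ndarray:
    """Two O-H offsets (nm) of a rigid 3-site water, randomly oriented."""
    r_oh, half = 0.09572, math.radians(104.52 / 2.0)
    local = np.array([[r_oh * math.sin(half), 0.0, r_oh * math.cos(half)],
                      [-r_oh * math.sin(half), 0.0, r_oh * math.cos(half)]])
    # uniform random rotation from a random axis-angle pair (adequate here)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    k = axis
    kk = np.outer(k, k)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = math.cos(ang) * np.eye(3) + math.sin(ang) * kx + (1 - math.cos(ang)) * kk
    return local @ rot.T


def _water_lattice(box: np.ndarray, z_ranges: list[tuple[float, float]],
                   n_water: int, rng: np.random.Generator) -> np.ndarray:
    """Jittered-lattice water oxygen positions in the given z slabs."""
    vol = sum(box[0] * box[1] * (hi - lo) for lo, hi in z_ranges)
    if vol <= 0 or n_water <= 0:
        return np.empty((0, 3))
    spacing = (vol / n_water) ** (1.0 / 3.0)
    pts = []
    for lo, hi in z_ranges:
        nx = max(1, math.ceil(box[0] / spacing))
        ny = max(1, math.ceil(box[1] / spacing))
        nz = max(1, math.ceil((hi - lo) / spacing))
        xs = (np.arange(nx) + 0.5) * box[0] / nx
        ys = (np.arange(ny) + 0.5) * box[1] / ny
        zs = lo + (np.arange(nz) + 0.5) * (hi - lo) / nz
        grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
        pts.append(grid)
    pts = np.vstack(pts)
    if len(pts) < n_water:
        raise PackingError(
            f"water slabs fit only {len(pts)} of {n_water} molecules at "
            f"{n_water / vol:.1f} nm^-3; enlarge the box or water region")
    sel = rng.permutation(len(pts))[:n_water]
    jitter = rng.uniform(-0.12, 0.12, size=(n_water, 3)) * spacing * 0.4
    return pts[np.sort(sel)] + jitter


def pack_initial_configuration(comp: SystemComposition,
                               min_dist: float = 0.2,
                               seed: int = 0,
                               leaflet_separation: float = 3.8,
                               max_attempts: int = 5000) -> PackedFrame:
    """Pack an initial bilayer configuration by rejection sampling.

    Parameters
    ----------
    comp : SystemComposition
    min_dist : float
        Minimum allowed distance (nm) between particles of *different*
        lipids, periodic minimum-image convention (default 0.2 nm = 2 A).
    seed : int
        Output is bit-identical for a fixed seed and composition.
    leaflet_separation : float
        Initial distance between the two anchor (phosphate) planes, nm.
    max_attempts : int
        Placement attempts per lipid before giving up.

    Returns
    -------
    PackedFrame
        All coordinates wrapped inside the box; head groups face the two
        water slabs; OX3B fragments sit near the midplane sharing their
        parent's lipid ID.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(comp.box, dtype=float)
    z_mid = box[2] / 2.0
    z_up = z_mid + leaflet_separation / 2.0
    z_lo = z_mid - leaflet_separation / 2.0

    upper, lower = comp.per_leaflet()
    grid = _CellGrid(box, max(min_dist, 0.05))

    names, resnames, resids, lipid_ids, elements, masses = [], [], [], [], [], []
    coords: list[np.ndarray] = []
    leaflets: dict[int, str] = {}
    resid = 0
    lipid_id = 0

    def place_residue(template, base_coords, leaflet, plane_z, lid, rid):
        """Try random lateral placements until clash-free; append arrays."""
        anchor = anchor_index(template)
        for _ in range(max_attempts):
            rot = _rot_z(rng.uniform(0.0, 2.0 * math.pi))
            pts = base_coords @ rot.T
            target = np.array([rng.uniform(0.0, box[0]),
                               rng.uniform(0.0, box[1]),
                               plane_z + rng.uniform(-0.08, 0.08)])
            pts = pts - pts[anchor] + target
            pts[:, :2] %= box[:2]  # wrap laterally; z stays inside by design
            if not grid.clashes(pts, lid, min_dist):
                grid.add(pts, lid)
                coords.append(pts)
                names.extend(template.names)
                resnames.extend([template.species] * template.n_particles)
                resids.extend([rid] * template.n_particles)
                lipid_ids.extend([lid] * template.n_particles)
                elements.extend(p.element for p in template.particles)
                masses.extend(p.mass for p in template.particles)
                return
        area = box[0] * box[1]
        raise PackingError(
            f"could not place a {template.species} lipid after {max_attempts} "
            f"attempts (leaflet density "
            f"{sum(upper.values()) / area:.2f} lipids/nm^2, min_dist "
            f"{min_dist} nm)")

    for leaflet, split, plane_z in (("upper", upper, z_up), ("lower", lower, z_lo)):
        sign = 1.0 if leaflet == "upper" else -1.0
        for sp, n in split.items():
            is_pair = sp == "OX3"
            main = build_template("OX3A" if is_pair else sp)
            ref_main = reference_conformation(main)
            if leaflet == "lower":
                ref_main = ref_main @ _FLIP_X.T
            for _ in range(n):
                lipid_id += 1
                resid += 1
                leaflets[lipid_id] = leaflet
                place_residue(main, ref_main, leaflet, plane_z, lipid_id, resid)
                if is_pair:
                    frag = build_template("OX3B")
                    ref_frag = reference_conformation(frag)
                    resid += 1
                    # short-chain aldehyde starts in the core, below its
                    # parent's head group
                    place_residue(frag, ref_frag, leaflet,
                                  z_mid + sign * 0.55, lipid_id, resid)

    # water slabs outside the lipid region
    if comp.n_water > 0:
        head_clearance = 0.85
        margin = 0.05
        ranges = [(margin, max(margin, z_lo - head_clearance)),
                  (min(box[2] - margin, z_up + head_clearance), box[2] - margin)]
        ranges = [(lo, hi) for lo, hi in ranges if hi - lo > 0.3]
        o_pos = _water_lattice(box, ranges, comp.n_water, rng)
        for o in o_pos:
            h_off = _random_water_orientation(rng)
            mol = np.vstack([o, o + h_off[0], o + h_off[1]])
            mol %= box  # keep everything inside the box
            coords.append(mol)
            resid += 1
            for nm, el, m in (("OW", "O", ATOMIC_MASS["O"]),
                              ("HW1", "H", ATOMIC_MASS["H"]),
                              ("HW2", "H", ATOMIC_MASS["H"])):
                names.append(nm)
                resnames.append(WATER_RESNAME)
                resids.append(resid)
                lipid_ids.append(-1)
                elements.append(el)
                masses.append(m)

    top = Topology(np.array(names), np.array(resnames), np.array(resids),
                   np.array(lipid_ids), np.array(elements), np.array(masses))
    frame_coords = np.vstack(coords) if coords else np.empty((0, 3))
    return PackedFrame(top, frame_coords, box, leaflets=leaflets)
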