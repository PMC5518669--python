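"""Synthetic bilayer trajectories with known ground truth.

The generator emulates the statistical structure the analysis battery
assumes -- two phosphate planes a known distance apart, rigid all-trans sn-1
chains at a controlled tilt, NPT-like AR(1) fluctuations of the lateral box
area around a target area per lipid, bulk-packed water slabs and an optional
transmembrane water cylinder -- so every metric can be validated closed-loop
against construction truth without running molecular dynamics.

Chains are rigid (no intra-chain disorder): the expected chain-average order
parameter then has the exact closed form

    S_CD = -1/2 * P2(cos alpha),   P2(x) = (3 x^2 - 1)/2,

for a chain axis tilted by ``alpha`` from the membrane normal with uniform
random azimuth (the C-D bonds of an ideal zig-zag are exactly perpendicular
to the chain axis).  Defaults reproduce the study conditions: 72 lipids,
4000 waters, an 11 nm box height, frames every 100 ps, 1600 frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .builder import SystemComposition, make_composition
from .exceptions import CompositionError, TrajectoryError
from .frames import PackedFrame, Topology, Trajectory
from .topology import (ATOMIC_MASS, WATER_RESNAME, anchor_index,
                       build_template, reference_conformation)

#: Bulk water packing used for pore/bulk truths: 33.4 molecules nm^-3
#: (about 997 kg m^-3).
BULK_WATER_NUMBER_DENSITY = 33.4  # nm^-3
WATER_MOLECULE_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
AMU_PER_NM3_TO_KG_M3 = 1.66053907
BULK_WATER_MASS_DENSITY = (BULK_WATER_NUMBER_DENSITY * WATER_MOLECULE_MASS
                           * AMU_PER_NM3_TO_KG_M3)  # ~999 kg m^-3


def gen_ar1_series(n: int, mean: float, sigma: float, phi: float,
                   seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sigma`` and lag-1
    autocorrelation ``phi``; deterministic for a fixed seed."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= phi < 1.0:
        raise ValueError("phi must lie in [0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = mean + sigma * rng.standard_normal()
    innov_sd = sigma * math.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(n - 1) * innov_sd
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + eps[i - 1]
    return x


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic bilayer trajectory.

    leaflet_separation is the ground truth for the thickness analysis (the
    distance between the two phosphate planes); tilt_deg sets the S_CD truth
    through the closed form above; apl_truth (nm^2) fixes the mean lateral
    box area; pore_radius (Angstrom) optionally inserts a bulk-packed water
    cylinder through the core; polar_bend moves the peroxide/aldehyde marker
    oxygens of oxidized species from the core (straight, post-oxidation
    starting state) to just below the phosphate planes (bent, equilibrated
    state).
    """

    composition: SystemComposition = field(default_factory=make_composition)
    leaflet_separation: float = 3.8  # nm
    tilt_deg: float = 0.0
    apl_truth: float = 0.64  # nm^2
    area_rel_sigma: float = 0.01
    area_phi: float = 0.8
    pore_radius: float | None = None  # Angstrom
    polar_bend: bool = False
    n_frames: int = 1600
    frame_dt: float = 100.0  # ps
    seed: int = 0

    def __post_init__(self):
        if self.leaflet_separation <= 0 or self.apl_truth <= 0:
            raise ValueError("lengths and areas must be positive")
        if not 0.0 <= self.area_phi < 1.0:
            raise ValueError("area_phi must lie in [0, 1)")
        if self.area_rel_sigma < 0:
            raise ValueError("area_rel_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if self.pore_radius is not None and self.pore_radius <= 0:
            raise ValueError("pore_radius must be positive")
        box_z = self.composition.box[2]
        if self.leaflet_separation + 1.8 > box_z:
            raise ValueError("leaflet separation leaves no room for water "
                             f"slabs in a {box_z} nm box")
        if self.pore_radius is not None:
            n_pl = max(1, self.composition.n_per_leaflet)
            width = math.sqrt(self.apl_truth * n_pl)
            if 2 * self.pore_radius / 10.0 >= width:
                raise ValueError("pore wider than the lateral box")


@dataclass
class SyntheticTruth:
    """Construction ground truth accompanying a generated trajectory."""

    thickness: float  # nm, P-plane separation
    mean_scd: float  # closed-form chain-average S_CD
    areas: np.ndarray  # per-frame lateral box area, nm^2
    n_per_leaflet: int
    apl_requested: float  # nm^2
    water_core_density: float  # kg m^-3, geometric prediction in |z|<=0.5
    pore_diameter: float | None  # Angstrom (2 x pore_radius)
    bulk_water_density: float  # kg m^-3 of the generated bulk packing
    marker_abs_z: np.ndarray | None = None  # nm, |z| of polar markers

    def apl_series(self) -> np.ndarray:
        return self.areas / self.n_per_leaflet

    def to_dict(self) -> dict:
        d = asdict(self)
        d["areas"] = self.areas.tolist()
        if self.marker_abs_z is not None:
            d["marker_abs_z"] = self.marker_abs_z.tolist()
        return d


def _uniform_in_cylinder(n: int, radius: float, z_lo: float, z_hi: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Uniform random points in a z-aligned cylinder centred on the origin.

    At bulk water density this is far above the continuum-percolation
    threshold for the 0.35 nm linkage cutoff, so each frame's pore cluster
    spans the cylinder with near certainty.
    """
    rad = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    ang = rng.uniform(0.0, 2.0 * math.pi, n)
    z = rng.uniform(z_lo, z_hi, n)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang), z])


def _stratified_slab(lx: float, ly: float, z_lo: float, z_hi: float,
                     n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform in a slab, stratified along z.

    Stratification keeps the realized density in any z sub-slab within
    O(1/n) of the nominal value, so slab-density oracles are sharp.
    """
    if n <= 0 or z_hi <= z_lo:
        return np.empty((0, 3))
    z = z_lo + (np.arange(n) + rng.uniform(0.0, 1.0, n)) * (z_hi - z_lo) / n
    x = rng.uniform(0.0, lx, n)
    y = rng.uniform(0.0, ly, n)
    return np.column_stack([x, y, z])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


_FLIP_X = np.diag([1.0, -1.0, -1.0])


def _species_sequence(comp: SystemComposition) -> list[tuple[str, str, int]]:
    """(resname, leaflet, lipid_id) placement sequence; OX3 expands to a
    fragment pair sharing one lipid id."""
    upper, lower = comp.per_leaflet()
    seq = []
    lipid_id = 0
    for leaflet, split in (("upper", upper), ("lower", lower)):
        for sp, n in split.items():
            for _ in range(n):
                lipid_id += 1
                if sp == "OX3":
                    seq.append(("OX3A", leaflet, lipid_id))
                    seq.append(("OX3B", leaflet, lipid_id))
                else:
                    seq.append((sp, leaflet, lipid_id))
    return seq


def gen_bilayer_trajectory(spec: SyntheticSpec
                           ) -> tuple[Trajectory, SyntheticTruth]:
    """Generate a bilayer trajectory plus its construction ground truth.

    Phosphate anchors sit on two jittered planes at +/- leaflet_separation/2
    around the box centre; each lipid's rigid reference conformation is
    tilted by ``tilt_deg`` about a fresh uniform azimuth every frame; the
    lateral box follows an AR(1) law around apl_truth x n_per_leaflet; water
    fills the outer slabs (the whole box if the composition has no lipids)
    and, if requested, a bulk-packed cylinder through the core.

    Deterministic for a fixed spec (bit-identical coordinates per seed).
    """
    rng = np.random.default_rng(spec.seed)
    comp = spec.composition
    seq = _species_sequence(comp)
    n_pl = max(1, comp.n_per_leaflet)
    box_z = comp.box[2]
    z_mid = box_z / 2.0
    d_half = spec.leaflet_separation / 2.0
    alpha = math.radians(spec.tilt_deg)

    if comp.n_lipids_total > 0:
        mean_area = spec.apl_truth * n_pl
    else:  # pure-water box: keep the composition's lateral dimensions
        mean_area = comp.box[0] * comp.box[1]
    areas = gen_ar1_series(spec.n_frames, mean_area,
                           spec.area_rel_sigma * mean_area, spec.area_phi,
                           seed=int(rng.integers(2 ** 31 - 1))) \
        if spec.n_frames >= 2 else np.array([mean_area])
    areas = np.clip(areas, 0.25 * mean_area, 4.0 * mean_area)
    widths = np.sqrt(areas)

    templates = {name: build_template(name)
                 for name in {s for s, _, _ in seq}}
    refs = {name: reference_conformation(t) for name, t in templates.items()}

    # topology arrays
    names, resnames, resids, lipid_ids, elements, masses = [], [], [], [], [], []
    resid = 0
    lipid_slices: list[tuple[str, str, int, slice]] = []
    offset = 0
    for sp, leaflet, lid in seq:
        t = templates[sp]
        resid += 1
        names.extend(t.names)
        resnames.extend([sp] * t.n_particles)
        resids.extend([resid] * t.n_particles)
        lipid_ids.extend([lid] * t.n_particles)
        elements.extend(p.element for p in t.particles)
        masses.extend(p.mass for p in t.particles)
        lipid_slices.append((sp, leaflet, lid, slice(offset, offset + t.n_particles)))
        offset += t.n_particles

    # fractional lateral placement per residue, fixed over time
    frac_xy = rng.uniform(0.0, 1.0, size=(len(seq), 2))
    z_jitter = rng.normal(0.0, 0.02, size=len(seq))

    # water: outer slabs (or the full box when there are no lipids) + pore
    w0 = widths[0]
    water_o = []
    if comp.n_lipids_total == 0:
        water_o.append(_stratified_slab(w0, w0, 0.05, box_z - 0.05,
                                     comp.n_water, rng))
    elif comp.n_water > 0:
        clear = 0.9
        lo_rng = (0.05, z_mid - d_half - clear)
        hi_rng = (z_mid + d_half + clear, box_z - 0.05)
        v_lo = max(0.0, lo_rng[1] - lo_rng[0])
        v_hi = max(0.0, hi_rng[1] - hi_rng[0])
        n_lo = int(round(comp.n_water * v_lo / (v_lo + v_hi)))
        water_o.append(_stratified_slab(w0, w0, *lo_rng, n_lo, rng))
        water_o.append(_stratified_slab(w0, w0, *hi_rng, comp.n_water - n_lo, rng))
    n_pore = 0
    pore_span = (-(d_half + 0.15), d_half + 0.15)
    if spec.pore_radius is not None:
        r_nm = spec.pore_radius / 10.0
        n_pore = int(round(BULK_WATER_NUMBER_DENSITY * math.pi * r_nm ** 2
                           * (pore_span[1] - pore_span[0])))
        # placeholder positions; resampled fresh every frame below
        water_o.append(_uniform_in_cylinder(n_pore, r_nm, *pore_span, rng)
                       + np.array([w0 / 2.0, w0 / 2.0, z_mid]))
    water_o = np.vstack(water_o) if water_o else np.empty((0, 3))
    n_bulk = len(water_o) - n_pore

    # rigid three-site waters with per-molecule fixed random orientation
    r_oh, hh = 0.09572, math.radians(104.52 / 2.0)
    axes = rng.normal(size=(len(water_o), 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    # two O-H vectors in a random plane through each axis
    helper = rng.normal(size=(len(water_o), 3))
    perp = np.cross(axes, helper)
    nrm = np.linalg.norm(perp, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    perp /= nrm
    h1 = r_oh * (math.cos(hh) * axes + math.sin(hh) * perp)
    h2 = r_oh * (math.cos(hh) * axes - math.sin(hh) * perp)

    for _ in range(len(water_o)):
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
    n_particles = top.n_particles
    coords = np.empty((spec.n_frames, n_particles, 3))

    # per-frame assembly
    water_frac_xy = water_o[:, :2] / w0 if len(water_o) else None
    for f in range(spec.n_frames):
        w = widths[f]
        scale = w / w0
        frame = np.empty((n_particles, 3))
        for (sp, leaflet, lid, sl), fxy, zj in zip(lipid_slices, frac_xy,
                                                   z_jitter):
            t = templates[sp]
            ref = refs[sp]
            # spin about the molecular axis first, then tilt: the C-D bond
            # azimuth in the plane perpendicular to the chain axis is then
            # uniform, giving the closed-form rotational average for S_CD
            psi = rng.uniform(0.0, 2.0 * math.pi)
            rot = _rot_y(alpha) @ _rot_z(psi)
            pts = ref @ rot.T
            if leaflet == "lower":
                pts = pts @ _FLIP_X.T
            if sp == "OX3B":
                plane = z_mid + (0.25 if leaflet == "upper" else -0.25)
            else:
                plane = z_mid + (d_half if leaflet == "upper" else -d_half) + zj
            anchor = anchor_index(t)
            pts = pts - pts[anchor] + np.array(
                [fxy[0] * w, fxy[1] * w, plane])
            frame[sl] = pts
        if len(water_o):
            ow = np.empty_like(water_o)
            ow[:, 0] = water_frac_xy[:, 0] * w
            ow[:, 1] = water_frac_xy[:, 1] * w
            ow[:, 2] = water_o[:, 2]
            if n_pore:
                # resample the pore column every frame (bulk-density
                # disorder; the cylinder radius stays fixed in nm)
                cyl = _uniform_in_cylinder(n_pore, spec.pore_radius / 10.0,
                                           *pore_span, rng)
                ow[n_bulk:] = cyl + np.array([w / 2.0, w / 2.0, z_mid])
            wat = np.empty((3 * len(ow), 3))
            wat[0::3] = ow
            wat[1::3] = ow + h1
            wat[2::3] = ow + h2
            frame[n_particles - 3 * len(ow):] = wat
        coords[f] = frame

    # polar markers: straight (core) vs bent (near the phosphate planes)
    marker_abs_z = None
    marker_cols = []
    for sp, leaflet, lid, sl in lipid_slices:
        t = templates[sp]
        for mi in t.polar_marker_indices:
            sign = 1.0 if leaflet == "upper" else -1.0
            marker_cols.append((sl.start + mi, sign))
    if marker_cols:
        idx = np.array([c[0] for c in marker_cols])
        signs = np.array([c[1] for c in marker_cols])
        if spec.polar_bend:
            depth = d_half - 0.12
        else:
            depth = 0.0
        zvals = signs * depth + rng.normal(0.0, 0.03, size=(spec.n_frames,
                                                            len(idx)))
        coords[:, idx, 2] = z_mid + zvals
        marker_abs_z = np.abs(zvals).ravel()

    times = spec.frame_dt * (np.arange(spec.n_frames) + 1.0)
    boxes = np.column_stack([widths, widths, np.full(spec.n_frames, box_z)])
    traj = Trajectory(top, times, boxes, coords)

    has_sn1 = any(templates[s].sn1_chain for s in templates)
    p2 = 0.5 * (3.0 * math.cos(alpha) ** 2 - 1.0)
    mean_scd = -0.5 * p2 if has_sn1 else float("nan")
    if spec.pore_radius is not None:
        r_nm = spec.pore_radius / 10.0
        core = (BULK_WATER_NUMBER_DENSITY * math.pi * r_nm ** 2 * 1.0
                * WATER_MOLECULE_MASS / (mean_area * 1.0)
                * AMU_PER_NM3_TO_KG_M3)
        pore_diam = 2.0 * spec.pore_radius
    else:
        core, pore_diam = 0.0, None
    truth = SyntheticTruth(
        thickness=spec.leaflet_separation, mean_scd=mean_scd, areas=areas,
        n_per_leaflet=n_pl, apl_requested=spec.apl_truth,
        water_core_density=core, pore_diameter=pore_diam,
        bulk_water_density=BULK_WATER_MASS_DENSITY,
        marker_abs_z=marker_abs_z)
    return traj, truth


def gen_bent_tail_frame(spec: SyntheticSpec
                        ) -> tuple[PackedFrame, SyntheticTruth]:
    """Single frame with polar markers placed per the bend mode.

    In straight mode (the freshly oxidized state) the peroxide/aldehyde
    oxygens sit at the bilayer core; in bent mode (the equilibrated state)
    they sit just below the phosphate planes.  The truth record carries the
    marker |z| distribution so the marker density profile can be verified.
    """
    one = SyntheticSpec(**{**asdict_spec(spec), "n_frames": 1})
    traj, truth = gen_bilayer_trajectory(one)
    leaflets = {}
    for sp, leaflet, lid in _species_sequence(spec.composition):
        leaflets[lid] = leaflet
    frame = PackedFrame(traj.top, traj.coords[0], traj.boxes[0],
                        leaflets=leaflets)
    return frame, truth


def asdict_spec(spec: SyntheticSpec) -> dict:
    """Spec fields as a dict with the composition object preserved."""
    return {
        "composition": spec.composition,
        "leaflet_separation": spec.leaflet_separation,
        "tilt_deg": spec.tilt_deg,
        "apl_truth": spec.apl_truth,
        "area_rel_sigma": spec.area_rel_sigma,
        "area_phi": spec.area_phi,
        "pore_radius": spec.pore_radius,
        "polar_bend": spec.polar_bend,
        "n_frames": spec.n_frames,
        "frame_dt": spec.frame_dt,
        "seed": spec.seed,
    }
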