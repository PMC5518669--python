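"""File formats, run configuration and the analysis pipeline.

GRO (nm, fixed width) is the canonical interchange format; PDB (Angstrom)
is offered for visualization.  Multi-frame trajectories are read and written
through XTC/TRR.  All coordinate I/O is delegated to MDAnalysis behind this
module's surface; coordinates are stored in nm internally and z is the
membrane normal.

The OX3 fragment pair is written as two consecutive residues (OX3A then its
OX3B) with distinct residue ids; on reading, each OX3B is re-attached to the
immediately preceding OX3A through the shared in-memory lipid ID.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from . import metrics
from .builder import make_composition
from .exceptions import ConfigError, FileFormatError
from .frames import Frame, Topology, Trajectory
from .metrics import BilayerReport, analyze_bilayer
from .synth import SyntheticSpec, gen_bilayer_trajectory
from .topology import ATOMIC_MASS, WATER_RESNAME, template_registry

STRUCTURE_EXTENSIONS = {".gro", ".pdb"}
TRAJECTORY_EXTENSIONS = {".xtc", ".trr"}


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _diagnose_gro(path: Path) -> str:
    """Best-effort location of the first malformed record in a GRO file."""
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:  # pragma: no cover
        return str(exc)
    if not lines:
        return "file is empty"
    if len(lines) < 2:
        return "line 2: missing atom-count record"
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        return f"line 2: atom count is not an integer ({lines[1]!r})"
    if len(lines) < n_atoms + 3:
        return (f"line {len(lines)}: file truncated "
                f"({n_atoms} atoms declared)")
    for i in range(2, 2 + n_atoms):
        ln = lines[i]
        if len(ln) < 44:
            return f"line {i + 1}: record shorter than fixed width"
        try:
            float(ln[20:28]), float(ln[28:36]), float(ln[36:44])
        except ValueError:
            return f"line {i + 1}: malformed coordinate fields"
    try:
        [float(tok) for tok in lines[2 + n_atoms].split()]
    except ValueError:
        return f"line {3 + n_atoms}: malformed box record"
    return "unrecognized defect"


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            el = ch.upper()
            return el if el in ATOMIC_MASS else "C"
    return "C"


def topology_from_universe(u: "mda.Universe") -> Topology:
    """Build the internal particle table from an MDAnalysis universe.

    Masses and elements come from the species templates where the residue
    name is recognized; unknown residues fall back to element-from-name
    with a warning.
    """
    names = u.atoms.names.astype(str)
    resnames = u.atoms.resnames.astype(str)
    resids = u.atoms.resids.astype(np.int64)
    n = len(names)
    elements = np.empty(n, dtype=object)
    masses = np.empty(n, dtype=float)
    lipid_ids = np.empty(n, dtype=np.int64)
    registry = template_registry()

    unknown: set[str] = set()
    last_ox3a_lid = None
    lid_counter = 0
    for res in u.residues:
        sel = res.atoms.ix
        rn = str(res.resname)
        if rn == WATER_RESNAME:
            lipid_ids[sel] = -1
            for i in sel:
                elements[i] = _element_of(names[i])
                masses[i] = ATOMIC_MASS[elements[i]]
            continue
        if rn in registry:
            t = registry[rn]
            if len(sel) != t.n_particles:
                raise FileFormatError(
                    f"residue {rn} {res.resid} has {len(sel)} atoms; the "
                    f"{rn} template defines {t.n_particles}")
            for i, p in zip(sel, t.particles):
                elements[i] = p.element
                masses[i] = p.mass
            if rn == "OX3B":
                if last_ox3a_lid is None:
                    raise FileFormatError(
                        f"OX3B residue {res.resid} has no preceding OX3A "
                        "parent")
                lipid_ids[sel] = last_ox3a_lid
                last_ox3a_lid = None
            else:
                lid_counter += 1
                lipid_ids[sel] = lid_counter
                if rn == "OX3A":
                    last_ox3a_lid = lid_counter
        else:
            unknown.add(rn)
            lid_counter += 1
            lipid_ids[sel] = lid_counter
            for i in sel:
                elements[i] = _element_of(names[i])
                masses[i] = ATOMIC_MASS[elements[i]]
    if unknown:
        warnings.warn(
            f"unknown residue names {sorted(unknown)}: element and mass "
            "guessed from atom names", stacklevel=2)
    return Topology(names, resnames, resids, lipid_ids,
                    elements.astype(str), masses)


def _open_universe(path: Path, *traj_paths: Path) -> "mda.Universe":
    if path.suffix.lower() not in STRUCTURE_EXTENSIONS:
        raise FileFormatError(
            f"{path}: unrecognized structure extension (expected GRO or PDB)")
    if not path.exists():
        raise FileFormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FileFormatError(f"{path}: file is empty")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), *map(str, traj_paths))
    except FileFormatError:
        raise
    except Exception as exc:
        hint = ""
        if path.suffix.lower() == ".gro":
            hint = f" ({_diagnose_gro(path)})"
        raise FileFormatError(f"{path}: cannot parse{hint}") from exc


def read_frame(path) -> Frame:
    """Read a single GRO or PDB frame into internal (nm) representation."""
    path = Path(path)
    u = _open_universe(path)
    top = topology_from_universe(u)
    if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
        raise FileFormatError(f"{path}: missing or degenerate box")
    return Frame(top, u.atoms.positions.astype(float) / 10.0,
                 np.asarray(u.dimensions[:3], dtype=float) / 10.0)


def load_trajectory(structure, trajectory=None, dt: float = 100.0
                    ) -> Trajectory:
    """Load a trajectory (XTC/TRR over a GRO/PDB topology) or single frame.

    Frame times come from the trajectory file when present and increasing;
    otherwise they are synthesized as ``dt`` ps per frame.
    """
    structure = Path(structure)
    if trajectory is None:
        return Trajectory.from_frame(read_frame(structure))
    trajectory = Path(trajectory)
    if trajectory.suffix.lower() not in TRAJECTORY_EXTENSIONS:
        raise FileFormatError(
            f"{trajectory}: unrecognized trajectory extension "
            f"(expected XTC or TRR)")
    u = _open_universe(structure, trajectory)
    top = topology_from_universe(u)
    times, boxes, coords = [], [], []
    for ts in u.trajectory:
        times.append(float(ts.time))
        boxes.append(ts.dimensions[:3].astype(float) / 10.0)
        coords.append(ts.positions.astype(float) / 10.0)
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = dt * (np.arange(len(times)) + 1.0)
    return Trajectory(top, times, np.asarray(boxes), np.asarray(coords))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _universe_from_topology(top: Topology) -> "mda.Universe":
    resid_change = np.flatnonzero(np.diff(top.resids) != 0)
    starts = np.concatenate([[0], resid_change + 1])
    resindex = np.zeros(top.n_particles, dtype=int)
    for k, s in enumerate(starts):
        resindex[s:] = k
    u = mda.Universe.empty(top.n_particles, n_residues=len(starts),
                           atom_resindex=resindex, trajectory=True)
    u.add_TopologyAttr("names", top.names)
    u.add_TopologyAttr("resnames", top.resnames[starts])
    u.add_TopologyAttr("resids", top.resids[starts])
    return u


def write_frame(path, frame: Frame) -> None:
    """Write a frame as GRO (nm on disk / fixed width) or PDB (Angstrom)."""
    path = Path(path)
    if path.suffix.lower() not in STRUCTURE_EXTENSIONS:
        raise FileFormatError(
            f"{path}: unrecognized structure extension (expected GRO or PDB)")
    u = _universe_from_topology(frame.top)
    u.atoms.positions = frame.coords * 10.0
    u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(structure_path, traj_path, traj: Trajectory) -> None:
    """Write a trajectory as a GRO/PDB topology plus an XTC/TRR file."""
    traj_path = Path(traj_path)
    if traj_path.suffix.lower() not in TRAJECTORY_EXTENSIONS:
        raise FileFormatError(
            f"{traj_path}: unrecognized trajectory extension")
    write_frame(structure_path, traj.frame(0))
    u = _universe_from_topology(traj.top)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(traj_path), n_atoms=traj.top.n_particles) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i] * 10.0
                u.dimensions = [*(traj.boxes[i] * 10.0), 90.0, 90.0, 90.0]
                u.trajectory.ts.time = traj.times[i]
                u.trajectory.ts.frame = i
                w.write(u.atoms)


def write_profile_tsv(path, profile: metrics.DensityProfile,
                      label: str) -> None:
    header = (f"{label} mass density profile\n"
              "columns: z_nm (relative to phosphate midplane), "
              "density_kg_m3\n"
              f"bin_width_nm: {profile.bin_width:.6f}")
    np.savetxt(path, np.column_stack([profile.bin_centers, profile.density]),
               fmt="%.6f\t%.6f", header=header)


def write_scd_tsv(path, per_carbon: dict[int, float]) -> None:
    rows = np.array(sorted(per_carbon.items()), dtype=float)
    np.savetxt(path, rows, fmt="%d\t%.6f",
               header="sn-1 deuterium order parameters\n"
                      "columns: carbon_position (1 = ester carbonyl), "
                      "S_CD (dimensionless)")


def write_report(outdir, report: BilayerReport) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.txt").write_text(report.to_text())
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    kv = []
    for key, sub in report.to_dict().items():
        if isinstance(sub, dict) and "value" in sub:
            kv.append(f"{key} = {sub['value']:.6g} +- {sub['error']:.6g}")
    pore = report.pore
    kv.append(f"pore_spanning = {pore.spanning}")
    if pore.spanning:
        kv.append(f"pore_diameter_max_A = {pore.diameter_max:.3f}")
        kv.append(f"pore_diameter_min_A = {pore.diameter_min:.3f}")
    (outdir / "report.kv").write_text("\n".join(kv) + "\n")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS = dict(
    mode=None, outdir="oxbilayer_out", seed=0,
    # composition / synthesis
    n_lipids=72, chol_fraction=0.0, ox_fraction=0.0, ox_species=None,
    n_water=4000, box=(5.5, 5.5, 11.0),
    leaflet_separation=3.8, tilt_deg=0.0, apl=0.64,
    area_rel_sigma=0.01, area_phi=0.8, pore_radius=None, polar_bend=False,
    n_frames=1600, frame_dt=100.0, write_xtc=False,
    # analysis
    structure=None, trajectory=None, n_per_leaflet=None, equil_time=None,
    n_bins=100, half_width=0.5, link_cutoff=0.35, include_c2=True, dt=100.0,
)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``_CONFIG_DEFAULTS`` for keys).

    ``mode`` is either ``synth`` (generate a synthetic trajectory, then
    analyze it) or ``analyze`` (analyze coordinate files on disk).
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {**_CONFIG_DEFAULTS, **self.values}
        if merged["mode"] not in ("synth", "analyze"):
            raise ConfigError(
                "config key 'mode' is required and must be 'synth' or "
                "'analyze'")
        if merged["mode"] == "analyze" and merged["structure"] is None:
            raise ConfigError(
                "config key 'structure' is required in analyze mode")
        for key in ("chol_fraction", "ox_fraction"):
            if not 0.0 <= float(merged[key]) <= 1.0:
                raise ConfigError(f"config key '{key}' must lie in [0, 1]")
        if int(merged["n_bins"]) < 2:
            raise ConfigError("config key 'n_bins' must be >= 2")
        self.values = merged

    def __getattr__(self, key):
        try:
            return self.__dict__["values"][key]
        except KeyError as exc:
            raise AttributeError(key) from exc


def load_config(path=None, **overrides) -> RunConfig:
    """Read a YAML config file; keyword overrides win over file values."""
    values: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(values)


def run_pipeline(config: RunConfig) -> BilayerReport:
    """Execute build/synthesize -> analyze -> report end to end.

    Writes report.txt / report.json / report.kv, TSV density and S_CD
    profiles, and a log echoing the full configuration and seed into
    ``config.outdir``; identical configs produce identical artifacts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = ["oxbilayer pipeline log"]
    log.append("config:")
    for k in sorted(config.values):
        log.append(f"  {k}: {config.values[k]!r}")

    if config.mode == "synth":
        comp = make_composition(
            n_lipids=int(config.n_lipids),
            chol_fraction=float(config.chol_fraction),
            ox_fraction=float(config.ox_fraction),
            ox_species=config.ox_species,
            n_water=int(config.n_water), box=tuple(config.box))
        spec = SyntheticSpec(
            composition=comp,
            leaflet_separation=float(config.leaflet_separation),
            tilt_deg=float(config.tilt_deg), apl_truth=float(config.apl),
            area_rel_sigma=float(config.area_rel_sigma),
            area_phi=float(config.area_phi),
            pore_radius=config.pore_radius,
            polar_bend=bool(config.polar_bend),
            n_frames=int(config.n_frames), frame_dt=float(config.frame_dt),
            seed=int(config.seed))
        try:
            traj, truth = gen_bilayer_trajectory(spec)
        except Exception as exc:
            raise type(exc)(f"synthesis stage: {exc}") from exc
        n_per_leaflet = truth.n_per_leaflet
        (outdir / "truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")
        write_frame(outdir / "structure.gro", traj.frame(0))
        if config.write_xtc:
            write_trajectory(outdir / "structure.gro",
                             outdir / "trajectory.xtc", traj)
        log.append(f"synthesized {traj.n_frames} frames, "
                   f"{traj.top.n_particles} particles")
    else:
        try:
            traj = load_trajectory(config.structure, config.trajectory,
                                   dt=float(config.dt))
        except Exception as exc:
            raise type(exc)(f"input stage: {exc}") from exc
        if config.n_per_leaflet is not None:
            n_per_leaflet = int(config.n_per_leaflet)
        else:
            n_lip = traj.top.n_lipids()
            n_per_leaflet = n_lip - n_lip // 2
            log.append(f"n_per_leaflet derived from topology: "
                       f"{n_per_leaflet} (of {n_lip} lipids)")
        log.append(f"loaded {traj.n_frames} frames, "
                   f"{traj.top.n_particles} particles")

    try:
        report = analyze_bilayer(
            traj, n_per_leaflet=n_per_leaflet,
            equil_time=config.equil_time, n_bins=int(config.n_bins),
            half_width=float(config.half_width),
            link_cutoff=float(config.link_cutoff),
            include_c2=bool(config.include_c2))
    except Exception as exc:
        raise type(exc)(f"analysis stage: {exc}") from exc

    report.meta["seed"] = int(config.seed)
    write_report(outdir, report)
    write_profile_tsv(outdir / "density_phosphate.tsv",
                      metrics.density_profile(
                          traj, metrics.select_phosphorus,
                          int(config.n_bins), config.equil_time),
                      "phosphorus")
    write_profile_tsv(outdir / "density_water.tsv",
                      metrics.density_profile(
                          traj, metrics.select_water,
                          int(config.n_bins), config.equil_time),
                      "water")
    marker_mask = metrics.select_polar_markers(traj.top)
    if marker_mask.any():
        write_profile_tsv(outdir / "density_markers.tsv",
                          metrics.density_profile(
                              traj, marker_mask,
                              int(config.n_bins), config.equil_time),
                          "peroxide/aldehyde oxygens")
    write_scd_tsv(outdir / "scd_sn1.tsv", report.scd_per_carbon)
    log.append("wrote report.txt report.json report.kv and TSV profiles")
    (outdir / "pipeline.log").write_text("\n".join(log) + "\n")
    return report
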