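"""Bilayer trajectory analysis.

Implements the standard bilayer battery on united-atom trajectories:

* deuterium order parameter S_CD = <(3 cos^2 theta - 1)/2> of the sn-1
  (palmitoyl) chain, with deuteriums rebuilt geometrically (see
  :mod:`oxbilayer.topology`);
* area per lipid (lateral box area over lipids per leaflet) with a
  block-averaged error estimate (Hess block method);
* bilayer thickness as the peak-to-peak distance of the phosphorus density
  profile over 100 z-bins, error bar one bin width;
* mass density profiles along the membrane normal, recentred per frame on
  the instantaneous phosphate midplane and binned against the instantaneous
  box (NPT-safe fractional binning);
* water density in the membrane core (|z| <= 0.5 nm by default), the
  polarity measure of the hydrophobic interior;
* detection and sizing of transmembrane water pores by periodic
  single-linkage clustering of core waters.

All functions discard an initial equilibration stretch; by default the first
half of the recorded time span (the source simulations discard the first
80 of 160 ns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .exceptions import AnalysisError, TrajectoryError
from .frames import (Topology, Trajectory, frames_after_equilibration,
                     species_particle_indices)
from .topology import (DeuteriumGeometry, LipidTemplate, cd_unit_vectors,
                       template_registry)

AMU_PER_NM3_TO_KG_M3 = 1.66053907  # 1 amu/nm^3 in kg/m^3


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalarWithError:
    """A scalar estimate with an error bar and the method that produced it."""

    value: float
    error: float
    method: str  # "block" | "bin-width" | "none"

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("error must be >= 0")

    def __str__(self):
        return f"{self.value:g} +/- {self.error:g} ({self.method})"


@dataclass
class DensityProfile:
    """Mass density over z-bins, centred on the bilayer midplane.

    density is in kg m^-3; bin_centers in nm relative to the phosphate
    midplane.  The integral density x bin volume reproduces the (time-mean)
    selected mass by construction; :meth:`mass_conservation_error` reports
    the relative discrepancy.
    """

    n_bins: int
    bin_centers: np.ndarray  # nm
    density: np.ndarray  # kg m^-3
    bin_width: float  # nm (time-mean)
    mean_area: float  # nm^2 (time-mean lateral box area)
    selected_mass: float  # amu, total mass of the selection

    def __post_init__(self):
        if len(self.bin_centers) != self.n_bins or len(self.density) != self.n_bins:
            raise AnalysisError("profile arrays must have n_bins entries")
        if np.any(self.density < -1e-12):
            raise AnalysisError("densities must be non-negative")

    def integral_mass(self) -> float:
        """Sum of density x bin volume, converted back to amu."""
        bin_vol = self.mean_area * self.bin_width  # nm^3
        return float(np.sum(self.density) * bin_vol / AMU_PER_NM3_TO_KG_M3)

    def mass_conservation_error(self) -> float:
        """|integral - selected mass| / selected mass (0 for empty selection)."""
        if self.selected_mass == 0:
            return 0.0
        return abs(self.integral_mass() - self.selected_mass) / self.selected_mass


@dataclass
class OrderParameterResult:
    """Per-carbon and chain-averaged deuterium order parameters.

    Carbon positions are counted along the sn-1 chain with the ester
    carbonyl as position 1; CD2 positions 2..15 carry reconstructed
    deuteriums.  ``frame_means`` holds the per-frame chain averages, from
    which a standard error over frames can be formed.
    """

    per_carbon: dict[int, float]
    mean_scd: float
    frame_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_skipped_collinear: int = 0

    def frame_standard_error(self) -> float:
        t = len(self.frame_means)
        if t < 2:
            return float("nan")
        return float(np.std(self.frame_means, ddof=1) / np.sqrt(t))


@dataclass
class PoreReport:
    """Transmembrane water-defect characterization.

    ``spanning`` is None when the membrane span itself could not be resolved
    (no phosphate peaks); diameters are present only for spanning pores.
    """

    spanning: bool | None
    diameter_max: float | None = None  # Angstrom
    diameter_min: float | None = None  # Angstrom
    frame_of_onset: float | None = None  # ps
    n_spanning_frames: int = 0

    def __post_init__(self):
        if self.spanning is not True:
            if self.diameter_max is not None or self.diameter_min is not None:
                raise AnalysisError("diameters only valid for spanning pores")
        elif (self.diameter_max is not None and self.diameter_min is not None
              and self.diameter_min > self.diameter_max + 1e-9):
            raise AnalysisError("diameter_min must not exceed diameter_max")


@dataclass
class BilayerReport:
    """The four headline metrics plus the pore report."""

    area_per_lipid: ScalarWithError  # nm^2
    thickness: ScalarWithError  # nm
    mean_scd: ScalarWithError  # dimensionless
    water_core_density: ScalarWithError  # kg m^-3
    pore: PoreReport
    scd_per_carbon: dict[int, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "area_per_lipid_nm2": {"value": self.area_per_lipid.value,
                                   "error": self.area_per_lipid.error},
            "thickness_nm": {"value": self.thickness.value,
                             "error": self.thickness.error},
            "mean_scd": {"value": self.mean_scd.value,
                         "error": self.mean_scd.error},
            "water_core_density_kg_m3": {"value": self.water_core_density.value,
                                         "error": self.water_core_density.error},
            "scd_per_carbon": {str(k): v for k, v in self.scd_per_carbon.items()},
            "pore": {
                "spanning": self.pore.spanning,
                "diameter_max_A": self.pore.diameter_max,
                "diameter_min_A": self.pore.diameter_min,
                "frame_of_onset_ps": self.pore.frame_of_onset,
                "n_spanning_frames": self.pore.n_spanning_frames,
            },
            "meta": self.meta,
        }

    def to_text(self) -> str:
        lines = ["bilayer analysis report", "======================="]
        lines.append(f"area per lipid      : {self.area_per_lipid.value:8.4f} "
                     f"+/- {self.area_per_lipid.error:.4f} nm^2 "
                     f"({self.area_per_lipid.value * 100:.1f} A^2)")
        lines.append(f"bilayer thickness   : {self.thickness.value:8.4f} "
                     f"+/- {self.thickness.error:.4f} nm")
        lines.append(f"mean sn-1 S_CD      : {self.mean_scd.value:8.4f} "
                     f"+/- {self.mean_scd.error:.4f}")
        lines.append(f"core water density  : {self.water_core_density.value:8.4f} "
                     f"+/- {self.water_core_density.error:.4f} kg m^-3")
        if self.pore.spanning is None:
            lines.append("pore                : membrane span unresolved")
        elif self.pore.spanning:
            lines.append(
                f"pore                : spanning, diameter "
                f"{self.pore.diameter_min:.1f}..{self.pore.diameter_max:.1f} A, "
                f"onset {self.pore.frame_of_onset:g} ps "
                f"({self.pore.n_spanning_frames} frames)")
        else:
            lines.append("pore                : none (no spanning water cluster)")
        for k, v in sorted(self.meta.items()):
            lines.append(f"# {k}: {v}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def scd_from_cosines(cosines) -> float:
    """Order parameter <(3 cos^2 theta - 1)/2> from bond-angle cosines.

    Equals 1 when every C-D bond is parallel to the membrane normal
    (theta = 0) and -1/2 when every bond is perpendicular (theta = 90 deg);
    isotropic orientations average to 0.
    """
    c = np.asarray(cosines, dtype=float)
    if c.size == 0:
        raise AnalysisError("cannot average an empty list of cosines")
    if np.any(np.abs(c) > 1.0 + 1e-12):
        raise AnalysisError("cosines must lie in [-1, 1]")
    return float(np.mean(1.5 * np.clip(c, -1.0, 1.0) ** 2 - 0.5))


def relative_change(value: float, reference: float) -> float:
    """Percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise AnalysisError("relative change undefined for zero reference")
    return 100.0 * (value - reference) / reference


def block_error(series) -> ScalarWithError:
    """Error of the mean of a correlated series by the block method.

    The series is blocked at sizes 2^k; the blocked standard error of the
    mean is computed at each size and the large-block plateau is estimated
    by a weighted linear fit of SE^2 against 1/block_size over the larger
    block sizes (falling back to the maximum blocked SE if the fit
    degenerates).  For uncorrelated data this reduces to the naive
    sigma/sqrt(n); positively autocorrelated data yields a larger error.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 16:
        raise AnalysisError(f"block method needs >= 16 points, got {n}")
    mean = float(np.mean(x))
    sizes, se2, nblocks = [], [], []
    m = 1
    while n // m >= 4:
        nb = n // m
        bm = x[: nb * m].reshape(nb, m).mean(axis=1)
        var_bm = float(np.var(bm, ddof=1))
        sizes.append(m)
        se2.append(var_bm / nb)
        nblocks.append(nb)
        m *= 2
    sizes = np.array(sizes, dtype=float)
    se2 = np.array(se2)
    nblocks = np.array(nblocks, dtype=float)
    if np.allclose(se2, 0.0):
        return ScalarWithError(mean, 0.0, "block")

    # Two-parameter plateau fit: for exponential autocorrelation with
    # per-sample correlation c and marginal variance s2, the blocked SE^2
    # at block size m is exactly
    #   se2(m) = s2/n * [ (1+c)/(1-c) - 2 c (1-c^m) / (m (1-c)^2) ],
    # which rises from s2/n at m=1 to the plateau s2 (1+c)/(1-c) / n.
    # Fit (s2, c) over all block sizes, weighting each point by the
    # chi^2-based standard deviation of its variance estimate, and report
    # the fitted plateau; fall back to the maximum blocked SE if the fit
    # degenerates.
    def model(m, s2, c):
        c = np.clip(c, 0.0, 1.0 - 1e-9)
        return s2 / n * ((1 + c) / (1 - c)
                         - 2 * c * (1 - c ** m) / (m * (1 - c) ** 2))

    err = float(np.sqrt(np.max(se2)))  # fallback
    point_sd = se2 * np.sqrt(2.0 / (nblocks - 1.0))
    var0 = float(np.var(x, ddof=1))
    ac1 = float(np.corrcoef(x[:-1], x[1:])[0, 1]) if var0 > 0 else 0.0
    p0 = (var0, min(max(ac1, 0.0), 0.99))
    try:
        from scipy.optimize import curve_fit
        popt, _ = curve_fit(model, sizes, se2, p0=p0, sigma=point_sd,
                            bounds=([0.0, 0.0], [np.inf, 1.0 - 1e-9]),
                            maxfev=10000)
        s2_fit, c_fit = popt
        plateau = s2_fit * (1 + c_fit) / (1 - c_fit) / n
        if plateau > 0:
            err = float(np.sqrt(plateau))
    except (RuntimeError, ValueError):  # pragma: no cover - fit failure
        pass
    return ScalarWithError(mean, err, "block")


# ---------------------------------------------------------------------------
# trajectory helpers
# ---------------------------------------------------------------------------

def _wrap_centered(z: np.ndarray, lz: float) -> np.ndarray:
    """Wrap z into [-lz/2, lz/2)."""
    return (z + lz / 2.0) % lz - lz / 2.0


def _midplane_z(traj: Trajectory, used: np.ndarray) -> np.ndarray:
    """Per-used-frame z of the phosphate midplane (box-centre fallback)."""
    p_mask = traj.top.is_phosphorus
    if p_mask.any():
        return traj.coords[used][:, p_mask, 2].mean(axis=1)
    warnings.warn("no phosphorus particles; centring profiles on the box "
                  "centre", stacklevel=3)
    return traj.boxes[used][:, 2] / 2.0


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    if callable(selection):
        selection = selection(traj.top)
    mask = np.asarray(selection, dtype=bool)
    if mask.shape != (traj.top.n_particles,):
        raise AnalysisError("selection mask length must equal particle count")
    return mask


def select_phosphorus(top: Topology) -> np.ndarray:
    return top.is_phosphorus


def select_water(top: Topology) -> np.ndarray:
    return top.is_water


def select_polar_markers(top: Topology) -> np.ndarray:
    """Peroxide/aldehyde marker oxygens of all oxidized residues."""
    mask = np.zeros(top.n_particles, dtype=bool)
    for resname, template in template_registry().items():
        if not template.polar_marker_indices:
            continue
        mat = species_particle_indices(top, resname)
        if mat.size:
            mask[mat[:, list(template.polar_marker_indices)].ravel()] = True
    return mask


# ---------------------------------------------------------------------------
# the battery
# ---------------------------------------------------------------------------

def area_per_lipid(traj: Trajectory, n_per_leaflet: int,
                   equil_time: float | None = None) -> ScalarWithError:
    """Time-mean lateral box area divided by lipids per leaflet (nm^2).

    Cholesterol counts as a lipid and an OX3 fragment pair counts once;
    ``n_per_leaflet`` must already reflect that bookkeeping.  The error is
    the block-method error of the per-frame series.
    """
    if n_per_leaflet < 1:
        raise AnalysisError("n_per_leaflet must be >= 1")
    used = frames_after_equilibration(traj, equil_time)
    areas = traj.boxes[used, 0] * traj.boxes[used, 1]
    apl = areas / n_per_leaflet
    value = float(np.mean(apl))
    if len(apl) >= 16:
        err = block_error(apl).error
    else:
        err = float(np.std(apl, ddof=1) / np.sqrt(len(apl))) if len(apl) > 1 else 0.0
    return ScalarWithError(value, err, "block")


def order_parameter(traj: Trajectory,
                    templates: dict[str, LipidTemplate] | None = None,
                    equil_time: float | None = None,
                    include_c2: bool = True,
                    geometry: DeuteriumGeometry = DeuteriumGeometry()
                    ) -> OrderParameterResult:
    """sn-1 deuterium order parameter profile, averaged over the trajectory.

    For every lipid species with an sn-1 chain, deuterium directions are
    reconstructed on the CD2 carbons and cos(theta) is taken against the
    z axis (the membrane normal).  The average runs over both C-D bonds,
    all lipids of all such species, and all post-equilibration frames; the
    chain mean is the unweighted mean over carbon positions.

    ``include_c2`` controls whether the carbon adjacent to the ester
    carbonyl (position 2) enters the result.
    """
    if templates is None:
        templates = template_registry()
    used = frames_after_equilibration(traj, equil_time)
    coords = traj.coords[used]
    t_used = coords.shape[0]

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    frame_sum = np.zeros(t_used)
    frame_cnt = np.zeros(t_used)
    n_bad = 0
    found = False
    for resname, template in templates.items():
        chain = template.sn1_chain
        if len(chain) < 3:
            continue
        mat = species_particle_indices(traj.top, resname)
        if mat.size == 0:
            continue
        found = True
        chain_pos = coords[:, mat[:, list(chain)], :]  # (T, L, m, 3)
        d, valid = cd_unit_vectors(chain_pos, geometry)  # (T, L, m-2, 2, 3)
        n_bad += int((~valid).sum())
        p2 = 1.5 * d[..., 2] ** 2 - 0.5  # (T, L, m-2, 2)
        positions = np.arange(2, len(chain))  # carbon positions 2..m-1
        keep = np.ones(len(positions), dtype=bool)
        if not include_c2:
            keep &= positions != 2
        for j, pos in enumerate(positions):
            if not keep[j]:
                continue
            vals = p2[:, :, j, :][valid[:, :, j], :]
            if vals.size:
                sums[pos] = sums.get(pos, 0.0) + float(np.sum(vals))
                counts[pos] = counts.get(pos, 0) + vals.size
        vmask = valid[..., None] & np.ones_like(p2, dtype=bool)
        sel = np.where(keep)[0]
        frame_sum += np.nansum(np.where(vmask[:, :, sel, :],
                                        p2[:, :, sel, :], 0.0), axis=(1, 2, 3))
        frame_cnt += vmask[:, :, sel, :].sum(axis=(1, 2, 3))
    if not found:
        raise AnalysisError("trajectory contains no lipids with an sn-1 chain")
    if n_bad:
        warnings.warn(f"skipped {n_bad} collinear sn-1 carbons during "
                      "deuterium reconstruction", stacklevel=2)
    per_carbon = {pos: sums[pos] / counts[pos] for pos in sorted(sums)}
    if not per_carbon:
        raise AnalysisError("no usable CD2 carbons found")
    mean_scd = float(np.mean(list(per_carbon.values())))
    with np.errstate(invalid="ignore"):
        frame_means = np.where(frame_cnt > 0, frame_sum / frame_cnt, np.nan)
    return OrderParameterResult(per_carbon=per_carbon, mean_scd=mean_scd,
                                frame_means=frame_means,
                                n_skipped_collinear=n_bad)


def density_profile(traj: Trajectory, selection, n_bins: int = 100,
                    equil_time: float | None = None) -> DensityProfile:
    """Mass density of a particle selection over z-bins (kg m^-3).

    Each frame is recentred on its instantaneous phosphate midplane and
    binned fractionally against its instantaneous box height, so NPT-like
    box fluctuations do not smear the profile.  The reported density is the
    time-averaged bin mass over the time-averaged bin volume, which
    conserves the selected mass exactly.
    """
    if n_bins < 2:
        raise AnalysisError("n_bins must be >= 2")
    mask = _resolve_selection(traj, selection)
    used = frames_after_equilibration(traj, equil_time)
    lz = traj.boxes[used, 2]
    areas = traj.boxes[used, 0] * traj.boxes[used, 1]
    sel_mass = float(np.sum(traj.top.masses[mask]))
    if not mask.any():
        warnings.warn("empty selection: returning an all-zero profile",
                      stacklevel=2)
        mean_lz = float(np.mean(lz))
        centers = (np.arange(n_bins) + 0.5) * mean_lz / n_bins - mean_lz / 2.0
        return DensityProfile(n_bins, centers, np.zeros(n_bins),
                              mean_lz / n_bins, float(np.mean(areas)), 0.0)

    mid = _midplane_z(traj, used)
    masses = traj.top.masses[mask]
    t_used = int(used.sum())
    mass_per_bin = np.zeros(n_bins)
    for i in range(t_used):
        zrel = _wrap_centered(traj.coords[used][i, mask, 2] - mid[i], lz[i])
        frac = np.clip((zrel / lz[i] + 0.5) * n_bins, 0, n_bins - 1e-9)
        idx = frac.astype(int)
        mass_per_bin += np.bincount(idx, weights=masses, minlength=n_bins)
    mass_per_bin /= t_used

    mean_lz = float(np.mean(lz))
    mean_area = float(np.mean(areas))
    bin_width = mean_lz / n_bins
    # mean bin volume consistent with the fractional binning
    mean_bin_vol = float(np.mean(areas * lz)) / n_bins
    density = mass_per_bin / mean_bin_vol * AMU_PER_NM3_TO_KG_M3
    centers = (np.arange(n_bins) + 0.5) * bin_width - mean_lz / 2.0
    return DensityProfile(n_bins, centers, density, bin_width,
                          mean_bin_vol / bin_width, sel_mass)


def bilayer_thickness(p_profile: DensityProfile) -> ScalarWithError:
    """Peak-to-peak distance of the phosphorus density profile (nm).

    The thickness is z(upper-leaflet maximum) - z(lower-leaflet maximum);
    ties break toward larger |z|.  The error bar is one full bin width,
    reflecting the binning resolution of the peak positions.
    """
    z = p_profile.bin_centers
    d = p_profile.density
    lower = z < 0
    upper = ~lower
    if not d[lower].any() or not d[upper].any():
        raise AnalysisError(
            "cannot resolve two phosphate peaks (merged or missing leaflet)")

    def peak(side_mask, prefer_outward):
        vals = d[side_mask]
        zz = z[side_mask]
        best = vals.max()
        cand = np.flatnonzero(np.isclose(vals, best, rtol=0, atol=0))
        zc = zz[cand]
        return float(zc[np.argmax(np.abs(zc))]) if prefer_outward else float(zc[0])

    z_up = peak(upper, True)
    z_lo = peak(lower, True)
    if z_up - z_lo <= p_profile.bin_width:
        raise AnalysisError("phosphate peaks are not separated; "
                            "leaflets appear merged")
    return ScalarWithError(z_up - z_lo, p_profile.bin_width, "bin-width")


def water_density_center(traj: Trajectory, equil_time: float | None = None,
                         half_width: float = 0.5) -> ScalarWithError:
    """Water mass density in the inner membrane slab (kg m^-3).

    Averages the water mass found within |z - z_mid| <= half_width (default
    the inner 1 nm) over post-equilibration frames; the error is the block
    error of the per-frame series.  Used as the polarity measure of the
    membrane interior.
    """
    used = frames_after_equilibration(traj, equil_time)
    w = traj.top.is_water
    if not w.any():
        raise AnalysisError("no water residues in the system")
    mid = _midplane_z(traj, used)
    lz = traj.boxes[used, 2]
    areas = traj.boxes[used, 0] * traj.boxes[used, 1]
    masses = traj.top.masses[w]
    t_used = int(used.sum())
    series = np.zeros(t_used)
    for i in range(t_used):
        zrel = _wrap_centered(traj.coords[used][i, w, 2] - mid[i], lz[i])
        inside = np.abs(zrel) <= half_width
        vol = areas[i] * 2.0 * half_width
        series[i] = masses[inside].sum() / vol * AMU_PER_NM3_TO_KG_M3
    value = float(np.mean(series))
    if t_used >= 16:
        err = block_error(series).error
    elif t_used > 1:
        err = float(np.std(series, ddof=1) / np.sqrt(t_used))
    else:
        err = 0.0
    return ScalarWithError(value, err, "block")


def _cluster_labels(points: np.ndarray, box: np.ndarray,
                    cutoff: float) -> np.ndarray:
    """Single-linkage clusters under full periodic boundary conditions."""
    wrapped = points % box
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    n = len(points)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def detect_pore(traj: Trajectory, equil_time: float | None = None,
                link_cutoff: float = 0.35, slab_width: float = 0.1,
                water_volume: float = 0.030) -> PoreReport:
    """Detect and size a transmembrane water pore.

    Water oxygens between the two phosphate-peak planes are clustered by
    single linkage at ``link_cutoff`` (periodic minimum-image distances); a
    pore exists when one cluster touches both planes.  Slabs of
    ``slab_width`` along z are assigned an effective radius
    r = sqrt(n_waters * water_volume / (pi * slab_width)) from the
    time-averaged occupancy of the spanning cluster, and the reported
    diameters are twice the largest and smallest slab radii.
    """
    used = frames_after_equilibration(traj, equil_time)
    w = traj.top.is_water_oxygen
    if not w.any():
        raise AnalysisError("no water in the system")
    try:
        prof = density_profile(traj, select_phosphorus, equil_time=equil_time)
        thickness = bilayer_thickness(prof)
    except AnalysisError:
        return PoreReport(spanning=None)
    z_hi = thickness.value / 2.0
    z_lo = -z_hi  # peaks are symmetric around the recentred midplane
    # recover the actual peak positions (may be asymmetric)
    upper = prof.bin_centers > 0
    z_hi = float(prof.bin_centers[upper][np.argmax(prof.density[upper])])
    z_lo = float(prof.bin_centers[~upper][np.argmax(prof.density[~upper])])

    mid = _midplane_z(traj, used)
    times = traj.times[used]
    lz = traj.boxes[used, 2]
    n_slabs = max(1, int(round((z_hi - z_lo) / slab_width)))
    width = (z_hi - z_lo) / n_slabs
    slab_counts = np.zeros(n_slabs)
    n_spanning = 0
    onset = None
    t_used = int(used.sum())
    for i in range(t_used):
        pos = traj.coords[used][i, w, :].copy()
        zrel = _wrap_centered(pos[:, 2] - mid[i], lz[i])
        core = (zrel > z_lo) & (zrel < z_hi)
        if core.sum() == 0:
            continue
        pts = pos[core]
        labels = _cluster_labels(pts, traj.boxes[used][i], link_cutoff)
        zc = zrel[core]
        spanning_label = None
        for lab in np.unique(labels):
            sel = labels == lab
            if zc[sel].min() <= z_lo + link_cutoff and \
               zc[sel].max() >= z_hi - link_cutoff:
                spanning_label = lab
                break
        if spanning_label is None:
            continue
        n_spanning += 1
        if onset is None:
            onset = float(times[i])
        idx = np.clip(((zc[labels == spanning_label] - z_lo) / width)
                      .astype(int), 0, n_slabs - 1)
        slab_counts += np.bincount(idx, minlength=n_slabs)
    if n_spanning == 0:
        return PoreReport(spanning=False)
    mean_counts = slab_counts / n_spanning
    radii = np.sqrt(mean_counts * water_volume / (np.pi * width))  # nm
    return PoreReport(spanning=True,
                      diameter_max=float(2.0 * radii.max() * 10.0),
                      diameter_min=float(2.0 * radii.min() * 10.0),
                      frame_of_onset=onset,
                      n_spanning_frames=n_spanning)


def analyze_bilayer(traj: Trajectory, n_per_leaflet: int,
                    equil_time: float | None = None, n_bins: int = 100,
                    half_width: float = 0.5, link_cutoff: float = 0.35,
                    include_c2: bool = True) -> BilayerReport:
    """Run the full analysis battery and assemble a :class:`BilayerReport`."""
    apl = area_per_lipid(traj, n_per_leaflet, equil_time)
    p_prof = density_profile(traj, select_phosphorus, n_bins, equil_time)
    thickness = bilayer_thickness(p_prof)
    scd = order_parameter(traj, equil_time=equil_time, include_c2=include_c2)
    se = scd.frame_standard_error()
    scd_err = 0.0 if np.isnan(se) else se
    water = water_density_center(traj, equil_time, half_width)
    pore = detect_pore(traj, equil_time, link_cutoff)
    used = frames_after_equilibration(traj, equil_time)
    meta = {
        "n_frames_used": int(used.sum()),
        "n_frames_total": traj.n_frames,
        "equil_time_ps": equil_time,
        "n_per_leaflet": n_per_leaflet,
        "n_bins": n_bins,
        "half_width_nm": half_width,
        "link_cutoff_nm": link_cutoff,
        "include_c2": include_c2,
    }
    return BilayerReport(
        area_per_lipid=apl, thickness=thickness,
        mean_scd=ScalarWithError(scd.mean_scd, scd_err, "block"),
        water_core_density=water, pore=pore,
        scd_per_carbon=scd.per_carbon, meta=meta)
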