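"""Secondary-electron source: the per-proton phase space leaving the clusters.

A mono-energetic proton pencil beam (5 MeV, 17 µm diameter, travelling +Z)
crosses the cell.  Each geometric proton-nanoparticle traversal emits a
Poisson number of delta-ray electrons proportional to the chord length, with
energies from the close-collision 1/T² spectrum truncated at the two-body
kinematic maximum, and directions forward-biased about the beam axis.
Emitted electrons are attenuated along their exit ray through all
nanoparticle material they cross (intra- and inter-cluster); electrons
emerging below the tracking cutoff are counted as self-absorbed.  Gold
versus water-equivalent nanoparticles differ only through the emission
coefficient and the attenuation rate, which carry the material contrast
behind every enhancement ratio downstream.

The per-nanoparticle emission and attenuation coefficients are explicit
free parameters of the model, not first-principles gold cross-sections;
enhancement magnitudes therefore depend on them, while orderings (size,
distribution, material) are robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import CellModel, Compartment
from .distribution import ClusterSet
from .ranges import electron_range_um

__all__ = [
    "PROTON_MASS_MEV",
    "ELECTRON_MASS_KEV",
    "BeamSpec",
    "EmissionModel",
    "PhaseSpace",
    "ProtonTracks",
    "sample_proton_tracks",
    "kinematic_tmax",
    "emit_electrons",
    "primary_proton_dose",
]

PROTON_MASS_MEV = 938.272
ELECTRON_MASS_KEV = 510.999


def kinematic_tmax(energy_mev: float) -> float:
    """Maximum delta-ray energy (keV) for a proton of given kinetic energy.

    Free-electron two-body kinematics: Tmax = 2 m_e c² β²γ², with β²γ² =
    γ² - 1 from the proton kinetic energy.  5 MeV protons give ≈ 10.9 keV.
    """
    if energy_mev <= 0:
        raise ValueError("proton energy must be positive")
    gamma = 1.0 + energy_mev / PROTON_MASS_MEV
    return 2.0 * ELECTRON_MASS_KEV * (gamma**2 - 1.0)


@dataclass(frozen=True)
class BeamSpec:
    """Circular mono-energetic proton beam along +Z."""

    energy_mev: float = 5.0
    diameter_um: float = 17.0
    source_z_um: float = -12.0
    n_protons: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.diameter_um <= 0 or self.energy_mev <= 0:
            raise ValueError("beam diameter and energy must be positive")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")


@dataclass(frozen=True)
class ProtonTracks:
    """Straight +Z proton tracks; entry_xy holds the (x, y) of each track."""

    entry_xy: np.ndarray  # (n, 2) µm
    source_z_um: float
    energy_mev: float

    @property
    def n(self) -> int:
        return len(self.entry_xy)


def sample_proton_tracks(
    beam: BeamSpec, rng: np.random.Generator | None = None
) -> ProtonTracks:
    """Sample straight tracks with entry points uniform on the beam disc.

    5 MeV protons lose < 0.2 MeV and scatter negligibly over the 25 µm
    simulation box, so tracks are straight lines at constant energy.
    """
    rng = rng if rng is not None else np.random.default_rng(beam.seed)
    r = beam.diameter_um / 2.0 * np.sqrt(rng.random(beam.n_protons))
    phi = rng.uniform(0.0, 2.0 * np.pi, beam.n_protons)
    xy = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return ProtonTracks(xy, beam.source_z_um, beam.energy_mev)


@dataclass(frozen=True)
class EmissionModel:
    """Parameterised per-nanoparticle electron emission and self-absorption.

    ``emission_coeff_*`` is the expected number of emitted electrons per
    full-diameter proton traversal of one nanoparticle; the Poisson mean for
    a traversal scales with chord/diameter.  ``attenuation_*`` is the
    effective energy loss rate (keV/µm) of an electron crossing nanoparticle
    material.  Polar angles follow delta-ray ejection kinematics
    (cos θ = √(T/Tmax), so energetic electrons are strongly forward)
    smeared by a Gaussian of width ``1/sqrt(forward_bias_kappa)`` radians;
    ``forward_bias_kappa = 0`` gives an isotropic distribution.
    Electrons below ``cutoff_energy_kev`` (default 100 eV, range far below
    the 20 nm membrane thickness) are absorbed where they are.
    """

    tmax_kev: float = kinematic_tmax(5.0)
    spectrum_exponent: float = 2.0
    emission_coeff_gold: float = 8.0
    emission_coeff_water: float = 4.0
    forward_bias_kappa: float = 16.0
    attenuation_gold: float = 100.0  # keV/µm
    attenuation_water: float = 10.0  # keV/µm
    cutoff_energy_kev: float = 0.1

    def __post_init__(self):
        if self.tmax_kev <= 0:
            raise ValueError("tmax must be positive")
        if not (self.emission_coeff_gold > 0 and self.emission_coeff_water > 0):
            raise ValueError("emission coefficients must be positive")
        if self.attenuation_gold <= self.attenuation_water:
            raise ValueError("gold must attenuate faster than water")
        if not 0 < self.cutoff_energy_kev < self.tmax_kev:
            raise ValueError("cutoff must lie inside (0, tmax)")

    def coefficients(self, material: str) -> tuple[float, float]:
        if material == "gold":
            return self.emission_coeff_gold, self.attenuation_gold
        if material == "water":
            return self.emission_coeff_water, self.attenuation_water
        raise ValueError(f"unknown material {material!r}")


@dataclass
class PhaseSpace:
    """Escaping secondary electrons plus exact per-proton energy bookkeeping.

    emitted = escaped + self_absorbed holds exactly (in keV) per proton.
    """

    proton_id: np.ndarray  # (n,)
    cluster_id: np.ndarray  # (n,)
    positions: np.ndarray  # (n, 3) µm
    directions: np.ndarray  # (n, 3) unit
    energy_kev: np.ndarray  # (n,)
    n_protons: int
    emitted_kev_per_proton: np.ndarray  # (n_protons,)
    absorbed_kev_per_proton: np.ndarray  # (n_protons,)

    @property
    def n(self) -> int:
        return len(self.energy_kev)

    @property
    def escaped_kev_per_proton(self) -> np.ndarray:
        out = np.zeros(self.n_protons)
        np.add.at(out, self.proton_id, self.energy_kev)
        return out

    def to_csv(self, path, header_meta: dict | None = None) -> None:
        with open(path, "w") as fh:
            for k, v in (header_meta or {}).items():
                fh.write(f"# {k}: {v}\n")
            pd.DataFrame(
                {
                    "proton_id": self.proton_id,
                    "cluster_id": self.cluster_id,
                    "x": self.positions[:, 0],
                    "y": self.positions[:, 1],
                    "z": self.positions[:, 2],
                    "dx": self.directions[:, 0],
                    "dy": self.directions[:, 1],
                    "dz": self.directions[:, 2],
                    "energy_keV": self.energy_kev,
                }
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, n_protons: int) -> "PhaseSpace":
        df = pd.read_csv(path, comment="#")
        ps = cls(
            df["proton_id"].to_numpy(np.int64),
            df["cluster_id"].to_numpy(np.int64),
            df[["x", "y", "z"]].to_numpy(float),
            df[["dx", "dy", "dz"]].to_numpy(float),
            df["energy_keV"].to_numpy(float),
            n_protons,
            np.zeros(n_protons),
            np.zeros(n_protons),
        )
        return ps

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            proton_id=self.proton_id,
            cluster_id=self.cluster_id,
            positions=self.positions,
            directions=self.directions,
            energy_kev=self.energy_kev,
            n_protons=self.n_protons,
            emitted=self.emitted_kev_per_proton,
            absorbed=self.absorbed_kev_per_proton,
        )


def _sample_spectrum(
    rng: np.random.Generator, n: int, tmin: float, tmax: float, exponent: float
) -> np.ndarray:
    """Inverse-CDF sample of a T^-p spectrum truncated to [tmin, tmax]."""
    u = rng.random(n)
    if abs(exponent - 1.0) < 1e-12:
        return tmin * (tmax / tmin) ** u
    a = 1.0 - exponent
    return (u * (tmax**a - tmin**a) + tmin**a) ** (1.0 / a)


def _sample_forward_directions(
    rng: np.random.Generator,
    energy_kev: np.ndarray,
    tmax_kev: float,
    kappa: float,
) -> np.ndarray:
    """Delta-ray directions about +Z from free-electron kinematics.

    The polar angle follows the two-body ejection kinematics
    cos(theta) = sqrt(T / Tmax) — energetic delta rays are strongly
    forward, soft ones near-perpendicular — smeared by a Gaussian of
    width 1/sqrt(kappa) radians (multiple scattering inside the
    nanoparticle).  kappa = 0 disables the correlation and gives an
    isotropic distribution.
    """
    n = len(energy_kev)
    if kappa <= 1e-12:
        w = rng.uniform(-1.0, 1.0, n)
    else:
        theta = np.arccos(np.sqrt(np.clip(energy_kev / tmax_kev, 0.0, 1.0)))
        theta = theta + rng.normal(0.0, 1.0 / np.sqrt(kappa), n)
        w = np.cos(theta)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), w])


def _gold_path_lengths(
    origins: np.ndarray,
    directions: np.ndarray,
    clusters: ClusterSet,
    reach_um: np.ndarray | None = None,
) -> np.ndarray:
    """Total nanoparticle-material path length (µm) along each exit ray.

    Two-level test: ray against cluster bounding spheres first, then against
    the member nanoparticles of intersected clusters.  The ray starts on the
    emitting nanoparticle's surface heading outward, so its own chord is
    zero by construction.  ``reach_um`` caps the integration at each
    electron's water range: material beyond the distance the electron can
    travel cannot absorb it.
    """
    n = len(origins)
    out = np.zeros(n)
    if clusters.n_np == 0:
        return out
    if reach_um is None:
        reach_um = np.full(n, np.inf)
    c_centres = clusters.cluster_centres
    c_rad = clusters.cluster_diameter / 2.0 + clusters.np_radius
    r_np2 = clusters.np_radius**2
    order = np.argsort(clusters.np_cluster, kind="stable")
    sorted_pos = clusters.np_positions[order]
    bounds = np.searchsorted(
        clusters.np_cluster[order], np.arange(clusters.n_clusters + 1)
    )
    members = [
        sorted_pos[bounds[i] : bounds[i + 1]] for i in range(clusters.n_clusters)
    ]
    for e in range(n):
        p, d, cap = origins[e], directions[e], reach_um[e]
        oc = c_centres - p
        t_ca = oc @ d
        b2 = np.einsum("ij,ij->i", oc, oc) - t_ca**2
        half = c_rad**2 - b2
        hh = np.sqrt(np.clip(half, 0.0, None))
        hit = (half > 0.0) & (t_ca + hh > 0.0) & (t_ca - hh < cap)
        total = 0.0
        for ci in np.nonzero(hit)[0]:
            mc = members[ci] - p
            t = mc @ d
            bb = np.einsum("ij,ij->i", mc, mc) - t**2
            h2 = r_np2 - bb
            ok = h2 > 0.0
            if not ok.any():
                continue
            h = np.sqrt(h2[ok])
            # clip chords to [0, cap]: behind the origin or beyond the
            # electron's reach they cannot contribute
            t_in = np.clip(t[ok] - h, 0.0, cap)
            t_out = np.clip(t[ok] + h, 0.0, cap)
            total += float(np.sum(t_out - t_in))
        out[e] = total
    return out


def emit_electrons(
    tracks: ProtonTracks,
    clusters: ClusterSet,
    model: EmissionModel,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> PhaseSpace:
    """Generate the escaping secondary-electron phase space for all tracks.

    For every proton-nanoparticle traversal the electron count is
    Poisson(coeff · chord / diameter); energies follow the truncated 1/T²
    spectrum, directions the forward-biased axial distribution.  Each
    electron starts on the emitting nanoparticle's surface along its own
    direction and loses ``attenuation × path`` keV through all nanoparticle
    material on its way out; survivors below the cutoff are self-absorbed.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    coeff, atten = model.coefficients(clusters.material)
    n_protons = tracks.n
    emitted = np.zeros(n_protons)
    absorbed = np.zeros(n_protons)
    empty = PhaseSpace(
        np.empty(0, np.int64),
        np.empty(0, np.int64),
        np.empty((0, 3)),
        np.empty((0, 3)),
        np.empty(0),
        n_protons,
        emitted,
        absorbed,
    )
    if clusters.n_np == 0:
        return empty

    r_np = clusters.np_radius
    tree = cKDTree(clusters.np_positions[:, :2])
    hits = tree.query_ball_point(tracks.entry_xy, r_np)
    track_idx = np.fromiter(
        (i for i, h in enumerate(hits) for _ in h), dtype=np.int64
    )
    np_idx = np.fromiter((j for h in hits for j in h), dtype=np.int64)
    if len(np_idx) == 0:
        return empty

    dxy = tracks.entry_xy[track_idx] - clusters.np_positions[np_idx, :2]
    d2 = np.einsum("ij,ij->i", dxy, dxy)
    chord = 2.0 * np.sqrt(np.clip(r_np**2 - d2, 0.0, None))
    counts = rng.poisson(coeff * chord / (2.0 * r_np))
    if counts.sum() == 0:
        return empty

    e_proton = np.repeat(track_idx, counts)
    e_np = np.repeat(np_idx, counts)
    n_e = len(e_np)
    energy = _sample_spectrum(
        rng, n_e, model.cutoff_energy_kev, model.tmax_kev, model.spectrum_exponent
    )
    dirs = _sample_forward_directions(
        rng, energy, model.tmax_kev, model.forward_bias_kappa
    )
    origins = clusters.np_positions[e_np] + r_np * dirs

    np.add.at(emitted, e_proton, energy)
    path = _gold_path_lengths(origins, dirs, clusters, electron_range_um(energy))
    loss = np.minimum(atten * path, energy)
    e_out = energy - loss
    keep = e_out > model.cutoff_energy_kev
    # absorbed energy: the traversal loss for survivors, everything for drops
    np.add.at(absorbed, e_proton[keep], loss[keep])
    np.add.at(absorbed, e_proton[~keep], energy[~keep])

    return PhaseSpace(
        e_proton[keep],
        clusters.np_cluster[e_np[keep]],
        origins[keep],
        dirs[keep],
        e_out[keep],
        n_protons,
        emitted,
        absorbed,
    )


#: Default electronic stopping power of 5 MeV protons in water, keV/µm,
#: consistent with published range-energy tabulations to within a few %.
DEFAULT_STOPPING_POWER_KEV_UM = 8.0


def _clip_interval(lo, hi, track_q, axis_idx, cut_axis_idx, cut_sign, cut, centre_ax):
    """Intersect vertical-ray z-intervals with a planar-cut halfspace."""
    if cut_axis_idx == 2:
        # cut on z: clip the interval directly
        if cut_sign > 0:
            hi = np.minimum(hi, centre_ax + cut)
        else:
            lo = np.maximum(lo, centre_ax - cut)
    else:
        # cut on x (or y): the whole ray is in or out
        s = cut_sign * track_q
        outside = s > cut
        lo = np.where(outside, 0.0, lo)
        hi = np.where(outside, 0.0, hi)
    return lo, hi


def primary_proton_dose(
    tracks: ProtonTracks,
    cell: CellModel,
    stopping_power_kev_um: float = DEFAULT_STOPPING_POWER_KEV_UM,
) -> dict[Compartment, float]:
    """Energy (eV) deposited per proton in each compartment by the primaries.

    Deposits continuously at constant stopping power along each straight
    track; per-compartment chord lengths are computed analytically from the
    sphere/ellipsoid intersections of each vertical ray (exact, including
    planar cuts).  Used for the macroscale context only: enhancement ratios
    consider the nanoparticle-electron contribution alone.
    """
    cx, cy, cz = cell.centre
    x = tracks.entry_xy[:, 0] - cx
    y = tracks.entry_xy[:, 1] - cy
    rho2 = x**2 + y**2

    def sphere_halfwidth(R):
        return np.sqrt(np.clip(R**2 - rho2, 0.0, None))

    def ellipsoid_halfwidth(axes):
        a, b, c = axes
        val = 1.0 - (x / a) ** 2 - (y / b) ** 2
        return c * np.sqrt(np.clip(val, 0.0, None))

    h_nuc = sphere_halfwidth(cell.nucleus_radius)
    h_nm = sphere_halfwidth(cell.nuclear_membrane_outer_radius)
    h_in = ellipsoid_halfwidth(cell.inner_semi_axes)
    h_out = ellipsoid_halfwidth(cell.semi_axes)

    intervals = {}
    for name, h in (("nuc", h_nuc), ("nm", h_nm), ("in", h_in), ("out", h_out)):
        intervals[name] = (cz - h, cz + h)

    if cell.cut_axis is not None:
        from .geometry import _AXIS_INDEX

        ai = _AXIS_INDEX[cell.cut_axis]
        track_q = x if ai == 0 else (y if ai == 1 else None)
        for name, cut in (("out", cell.planar_cut_outer), ("in", cell.planar_cut_inner)):
            lo, hi = intervals[name]
            lo, hi = _clip_interval(
                lo, hi, track_q, 2, ai, cell.cut_sign, cut, cz
            )
            intervals[name] = (lo, hi)

    def length(name):
        lo, hi = intervals[name]
        return np.clip(hi - lo, 0.0, None)

    l_nuc = length("nuc")
    l_nm = length("nm") - l_nuc
    l_cyt = np.clip(length("in") - length("nm"), 0.0, None)
    l_mem = np.clip(length("out") - length("in"), 0.0, None)

    s_ev = stopping_power_kev_um * 1e3
    n = tracks.n
    return {
        Compartment.NUCLEUS: s_ev * float(l_nuc.sum()) / n,
        Compartment.NUCLEAR_MEMBRANE: s_ev * float(l_nm.sum()) / n,
        Compartment.CYTOPLASM: s_ev * float(l_cyt.sum()) / n,
        Compartment.CELL_MEMBRANE: s_ev * float(l_mem.sum()) / n,
    }
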