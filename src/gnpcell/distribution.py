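"""Nanoparticle cluster packing and intracellular placement.

Clusters of 15 nm nanoparticles (gold, or water-equivalent for the null
baseline) are packed by random sequential addition into spheres of 100, 200
or 500 nm diameter and placed uniformly either in a perinuclear shell (the
cytoplasm within 1 or 2.25 µm of the nuclear membrane) or throughout the
whole cytoplasm, without overlapping each other, the membranes or the
nucleus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CellModel, Compartment, GeometryError

__all__ = [
    "NP_RADIUS_UM",
    "Cluster",
    "ClusterSet",
    "DistributionSpec",
    "PackingError",
    "PlacementError",
    "pack_cluster",
    "place_clusters",
]

#: Radius of a single 15 nm nanoparticle, µm.
NP_RADIUS_UM = 0.0075

# Random sequential addition of hard spheres jams near 38% volume fraction;
# stay safely below it when validating a packing request.
_RSA_JAMMING_FRACTION = 0.30
_MAX_ATTEMPTS_PER_ITEM = 10_000


class PackingError(RuntimeError):
    """Packing could not be completed; carries the achieved count."""

    def __init__(self, msg: str, achieved: int = 0):
        super().__init__(msg)
        self.achieved = achieved


class PlacementError(RuntimeError):
    """Cluster placement could not be completed; carries the achieved count."""

    def __init__(self, msg: str, achieved: int = 0):
        super().__init__(msg)
        self.achieved = achieved


@dataclass(frozen=True)
class Cluster:
    """One nanoparticle cluster: a sphere of non-overlapping member NPs."""

    centre: np.ndarray  # (3,) µm
    diameter: float  # µm
    positions: np.ndarray  # (n, 3) absolute member centres, µm
    np_radius: float = NP_RADIUS_UM
    material: str = "gold"

    @property
    def n_np(self) -> int:
        return len(self.positions)


@dataclass
class ClusterSet:
    """All clusters of a run, flattened to arrays for fast geometry queries."""

    cluster_centres: np.ndarray  # (k, 3) µm
    cluster_diameter: float  # µm (uniform within a run)
    np_positions: np.ndarray  # (N, 3) µm
    np_cluster: np.ndarray  # (N,) int cluster index
    np_radius: float = NP_RADIUS_UM
    material: str = "gold"

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_centres)

    @property
    def n_np(self) -> int:
        return len(self.np_positions)

    def clusters(self):
        for i in range(self.n_clusters):
            sel = self.np_cluster == i
            yield Cluster(
                self.cluster_centres[i],
                self.cluster_diameter,
                self.np_positions[sel],
                self.np_radius,
                self.material,
            )

    # CSV round trip: one row per nanoparticle.
    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            {
                "cluster_id": self.np_cluster,
                "np_id": np.arange(self.n_np),
                "x": self.np_positions[:, 0],
                "y": self.np_positions[:, 1],
                "z": self.np_positions[:, 2],
                "radius": np.full(self.n_np, self.np_radius),
                "material": np.full(self.n_np, self.material),
            }
        )
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, cluster_diameter: float) -> "ClusterSet":
        df = pd.read_csv(path_or_buf)
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
        cid = df["cluster_id"].to_numpy(dtype=np.int64)
        n_clusters = int(cid.max()) + 1 if len(cid) else 0
        centres = np.zeros((n_clusters, 3))
        for i in range(n_clusters):
            centres[i] = pos[cid == i].mean(axis=0)
        material = str(df["material"].iloc[0]) if len(df) else "gold"
        radius = float(df["radius"].iloc[0]) if len(df) else NP_RADIUS_UM
        return cls(centres, cluster_diameter, pos, cid, radius, material)


@dataclass(frozen=True)
class DistributionSpec:
    """How many clusters of what size go where.

    ``region`` is ``"perinuclear"`` (with ``shell_width_um``, 1.0 or 2.25 µm
    in the study scenarios) or ``"whole_cytoplasm"``.
    """

    n_clusters: int
    cluster_diameter_um: float
    n_np_per_cluster: int
    region: str = "perinuclear"
    shell_width_um: float = 1.0
    seed: int = 0
    material: str = "gold"

    def __post_init__(self):
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.region not in ("perinuclear", "whole_cytoplasm"):
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def total_np(self) -> int:
        return self.n_clusters * self.n_np_per_cluster


def _sample_in_sphere(rng: np.random.Generator, radius: float, n: int) -> np.ndarray:
    """Uniform points in a sphere of given radius about the origin."""
    u = rng.random(n)
    r = radius * np.cbrt(u)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v


def pack_cluster(
    diameter: float,
    n_np: int,
    seed: int | np.random.Generator,
    np_radius: float = NP_RADIUS_UM,
    material: str = "gold",
) -> Cluster:
    """Pack ``n_np`` non-overlapping nanoparticles into a sphere at the origin.

    Random sequential addition: candidate centres are drawn uniformly in the
    sphere of radius ``diameter/2 - np_radius`` and accepted if at least
    ``2*np_radius`` from every accepted centre.  Deterministic for a given
    integer seed.  Raises :class:`PackingError` (reporting the achieved
    count) if the volume fraction is infeasible or attempts are exhausted.
    """
    if n_np < 0:
        raise ValueError("n_np must be >= 0")
    if diameter <= 2 * np_radius and n_np > 0:
        raise PackingError("cluster smaller than one nanoparticle", 0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_np == 0:
        return Cluster(np.zeros(3), diameter, np.empty((0, 3)), np_radius, material)

    r_avail = diameter / 2.0 - np_radius
    frac = n_np * (np_radius / r_avail) ** 3
    if frac > _RSA_JAMMING_FRACTION:
        raise PackingError(
            f"requested packing fraction {frac:.2f} exceeds the random "
            f"sequential addition limit {_RSA_JAMMING_FRACTION}",
            0,
        )

    accepted = np.empty((n_np, 3))
    n_acc = 0
    min_d2 = (2.0 * np_radius) ** 2
    attempts = 0
    max_attempts = _MAX_ATTEMPTS_PER_ITEM * n_np
    batch = max(2 * n_np, 64)
    while n_acc < n_np:
        cands = _sample_in_sphere(rng, r_avail, batch)
        for c in cands:
            attempts += 1
            if n_acc:
                d2 = np.einsum(
                    "ij,ij->i", accepted[:n_acc] - c, accepted[:n_acc] - c
                )
                if d2.min() < min_d2:
                    if attempts > max_attempts:
                        raise PackingError(
                            f"packing stalled after {attempts} attempts", n_acc
                        )
                    continue
            accepted[n_acc] = c
            n_acc += 1
            if n_acc == n_np:
                break
    return Cluster(np.zeros(3), diameter, accepted, np_radius, material)


def _sample_region_centres(
    rng: np.random.Generator,
    spec: DistributionSpec,
    cell: CellModel,
    n: int,
) -> np.ndarray:
    """Draw candidate cluster centres uniformly in the allowed region."""
    r_c = spec.cluster_diameter_um / 2.0
    t = cell.membrane_thickness
    r_lo = cell.nuclear_membrane_outer_radius + r_c
    if spec.region == "perinuclear":
        # entire cluster inside the shell of width w outside the nuclear
        # membrane: centre radius in [R_nm + r_c, R_nm + w - r_c]
        r_hi = cell.nuclear_membrane_outer_radius + spec.shell_width_um - r_c
        if r_hi <= r_lo:
            raise PlacementError("perinuclear shell too narrow for this cluster size")
        u = rng.random(n)
        r = np.cbrt(u * (r_hi**3 - r_lo**3) + r_lo**3)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        cands = np.asarray(cell.centre) + r[:, None] * v
    else:
        inner = np.asarray(cell.inner_semi_axes)
        lo = np.asarray(cell.centre) - inner
        hi = np.asarray(cell.centre) + inner
        cands = rng.uniform(lo, hi, size=(n, 3))
        q = cands - np.asarray(cell.centre)
        keep = np.einsum("ij,ij->i", q, q) >= r_lo**2
        cands = cands[keep]
    # common constraints: cluster fully inside the (possibly cut) cytoplasm
    q = cands - np.asarray(cell.centre)
    shrunk = np.asarray(cell.inner_semi_axes) - r_c
    ok = np.einsum("ij,ij->i", q / shrunk, q / shrunk) < 1.0
    if cell.cut_axis is not None:
        from .geometry import _AXIS_INDEX

        s = cell.cut_sign * q[:, _AXIS_INDEX[cell.cut_axis]]
        ok &= s <= cell.planar_cut_inner - r_c
    return cands[ok]


def place_clusters(spec: DistributionSpec, cell: CellModel) -> ClusterSet:
    """Place and pack all clusters of ``spec`` inside ``cell``.

    Cluster centres are uniform in the allowed region, clusters are pairwise
    non-overlapping (contact allowed) and entirely within the cytoplasm.
    Deterministic per ``spec.seed``; member packings use per-cluster child
    seeds spawned from the placement seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    place_rng = np.random.default_rng(ss.spawn(1)[0])
    r_c = spec.cluster_diameter_um / 2.0

    if spec.n_clusters == 0:
        return ClusterSet(
            np.empty((0, 3)),
            spec.cluster_diameter_um,
            np.empty((0, 3)),
            np.empty(0, dtype=np.int64),
            material=spec.material,
        )

    # cheap infeasibility check before attempting the packing
    r_nm = cell.nuclear_membrane_outer_radius
    if spec.region == "perinuclear":
        vol_region = 4.0 / 3.0 * np.pi * ((r_nm + spec.shell_width_um) ** 3 - r_nm**3)
    else:
        a, b, c = cell.inner_semi_axes
        vol_region = 4.0 / 3.0 * np.pi * (a * b * c - r_nm**3)
    frac = spec.n_clusters * 4.0 / 3.0 * np.pi * r_c**3 / vol_region
    if frac > _RSA_JAMMING_FRACTION:
        raise PlacementError(
            f"cluster volume fraction {frac:.2f} in the target region exceeds "
            f"the random sequential addition limit {_RSA_JAMMING_FRACTION}",
            0,
        )

    centres = np.empty((spec.n_clusters, 3))
    n_acc = 0
    min_d2 = (2.0 * r_c) ** 2
    attempts = 0
    max_attempts = _MAX_ATTEMPTS_PER_ITEM * spec.n_clusters
    while n_acc < spec.n_clusters:
        cands = _sample_region_centres(
            place_rng, spec, cell, max(2 * (spec.n_clusters - n_acc), 64)
        )
        if len(cands) == 0:
            attempts += 64
        for c in cands:
            attempts += 1
            if n_acc:
                d2 = np.einsum("ij,ij->i", centres[:n_acc] - c, centres[:n_acc] - c)
                if d2.min() < min_d2:
                    if attempts > max_attempts:
                        raise PlacementError(
                            f"placement stalled after {attempts} attempts", n_acc
                        )
                    continue
            centres[n_acc] = c
            n_acc += 1
            if n_acc == spec.n_clusters:
                break
        if attempts > max_attempts and n_acc < spec.n_clusters:
            raise PlacementError(
                f"region too small: placed {n_acc} of {spec.n_clusters}", n_acc
            )

    pack_seeds = ss.spawn(spec.n_clusters + 1)[1:]
    all_pos = np.empty((spec.total_np, 3))
    np_cluster = np.repeat(
        np.arange(spec.n_clusters, dtype=np.int64), spec.n_np_per_cluster
    )
    k = spec.n_np_per_cluster
    for i in range(spec.n_clusters):
        cl = pack_cluster(
            spec.cluster_diameter_um,
            k,
            np.random.default_rng(pack_seeds[i]),
            material=spec.material,
        )
        all_pos[i * k : (i + 1) * k] = cl.positions + centres[i]
    return ClusterSet(
        centres,
        spec.cluster_diameter_um,
        all_pos,
        np_cluster,
        material=spec.material,
    )
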