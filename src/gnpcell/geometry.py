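"""Cell geometry: ellipsoidal cell, membrane shells, spherical nucleus.

The model cell is a general ellipsoid (one 11 µm semi-axis along the beam,
two 7.5 µm semi-axes) containing a centred 5 µm-radius spherical nucleus.
Both the cell and nuclear membranes are 20 nm shells: the nuclear membrane
extends outward from the nucleus radius, the cell membrane extends inward
from the outer ellipsoid, so the stated outer dimensions of both the cell
and the nucleus are preserved.  All coordinates are continuous 3-D positions
in micrometres with the cell centre at the origin.

Two-cell arrangements (compressed / touching / separated, along the beam
axis Z or perpendicular axis X) are expressed as :class:`MultiCellLayout`;
compressed cells carry planar cuts on their facing sides that flatten the
membrane into a 20 nm slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Compartment",
    "CellModel",
    "MultiCellLayout",
    "GeometryError",
    "classify_point",
    "compartment_volume",
    "build_layout",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class GeometryError(ValueError):
    """Raised for invalid geometric configurations or inputs."""


class Compartment(IntEnum):
    """Mutually exclusive cell compartments; every point gets exactly one."""

    EXTRACELLULAR = 0
    CELL_MEMBRANE = 1
    CYTOPLASM = 2
    NUCLEAR_MEMBRANE = 3
    NUCLEUS = 4


@dataclass(frozen=True)
class CellModel:
    """Ellipsoidal cell with a centred spherical nucleus.

    Parameters
    ----------
    centre:
        Cell (and nucleus) centre, µm.
    semi_axes:
        Outer ellipsoid semi-axes (a, b, c) µm; ``c`` is beam-parallel (Z).
    nucleus_radius:
        Nucleus sphere radius, µm.
    membrane_thickness:
        Thickness of both membrane shells, µm.
    cut_axis, cut_sign, planar_cut_outer, planar_cut_inner:
        Optional planar truncation used for compressed two-cell layouts:
        the outer cell boundary is clipped at ``cut_sign * (p - centre)``
        along ``cut_axis`` at ``planar_cut_outer`` and the inner cytoplasm
        boundary at ``planar_cut_inner``; their difference must equal the
        membrane thickness so the flat face keeps a 20 nm membrane slab.
    """

    centre: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes: tuple[float, float, float] = (7.5, 7.5, 11.0)
    nucleus_radius: float = 5.0
    membrane_thickness: float = 0.02
    cut_axis: str | None = None
    cut_sign: int = 1
    planar_cut_outer: float | None = None
    planar_cut_inner: float | None = None

    def __post_init__(self) -> None:
        if self.membrane_thickness <= 0:
            raise GeometryError("membrane_thickness must be positive")
        t = self.membrane_thickness
        if self.nucleus_radius + t >= min(self.semi_axes) - t:
            raise GeometryError(
                "nucleus plus nuclear membrane must fit inside the inner "
                "cytoplasm boundary"
            )
        has_cut = self.cut_axis is not None
        if has_cut != (self.planar_cut_outer is not None) or has_cut != (
            self.planar_cut_inner is not None
        ):
            raise GeometryError("planar cut requires axis, outer and inner values")
        if has_cut:
            if self.cut_axis not in _AXIS_INDEX:
                raise GeometryError(f"unknown cut axis {self.cut_axis!r}")
            if self.cut_sign not in (-1, 1):
                raise GeometryError("cut_sign must be +1 or -1")
            if not np.isclose(self.planar_cut_outer - self.planar_cut_inner, t):
                raise GeometryError(
                    "planar_cut_outer - planar_cut_inner must equal the "
                    "membrane thickness"
                )
            if self.planar_cut_inner < self.nucleus_radius + t:
                raise GeometryError(
                    "planar cut would intersect the nucleus or nuclear membrane"
                )

    # -- derived geometry -------------------------------------------------

    @property
    def inner_semi_axes(self) -> tuple[float, float, float]:
        """Semi-axes of the inner cytoplasm boundary (outer minus 20 nm)."""
        t = self.membrane_thickness
        return tuple(a - t for a in self.semi_axes)

    @property
    def nuclear_membrane_outer_radius(self) -> float:
        return self.nucleus_radius + self.membrane_thickness

    def outer_volume(self) -> float:
        """Volume of the (uncut) outer ellipsoid, µm³."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def nucleus_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.nucleus_radius**3

    # -- classification ---------------------------------------------------

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Classify points (n, 3) µm into compartments.

        Returns an int array of :class:`Compartment` values.  Raises
        :class:`GeometryError` on non-finite coordinates.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError("points must have shape (n, 3)")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("non-finite coordinates")
        q = pts - np.asarray(self.centre)

        r2 = np.einsum("ij,ij->i", q, q)
        in_nucleus = r2 < self.nucleus_radius**2
        in_nm = r2 < self.nuclear_membrane_outer_radius**2

        outer = np.asarray(self.semi_axes)
        inner = np.asarray(self.inner_semi_axes)
        m_out = np.einsum("ij,ij->i", q / outer, q / outer)
        m_in = np.einsum("ij,ij->i", q / inner, q / inner)
        in_outer = m_out <= 1.0
        in_inner = m_in < 1.0
        if self.cut_axis is not None:
            s = self.cut_sign * q[:, _AXIS_INDEX[self.cut_axis]]
            in_outer &= s <= self.planar_cut_outer
            in_inner &= s < self.planar_cut_inner

        out = np.full(len(pts), int(Compartment.EXTRACELLULAR), dtype=np.int8)
        out[in_outer] = int(Compartment.CELL_MEMBRANE)
        out[in_inner] = int(Compartment.CYTOPLASM)
        out[in_nm] = int(Compartment.NUCLEAR_MEMBRANE)
        out[in_nucleus] = int(Compartment.NUCLEUS)
        return out

    def near_membrane(self, points: np.ndarray, margin: float) -> np.ndarray:
        """Conservative mask of points within ``margin`` µm of either membrane.

        Used to trigger refined sub-stepping in the chemistry stage; false
        positives only cost extra sub-steps, so the cell-membrane distance is
        a cheap scaled-ellipsoid bound rather than the exact normal distance.
        """
        q = np.atleast_2d(points) - np.asarray(self.centre)
        r = np.sqrt(np.einsum("ij,ij->i", q, q))
        t = self.membrane_thickness
        near = np.abs(r - (self.nucleus_radius + 0.5 * t)) < margin + 0.5 * t

        outer = np.asarray(self.semi_axes)
        m = np.sqrt(np.einsum("ij,ij->i", q / outer, q / outer))
        # scaled-radius gap underestimates the true distance by at most the
        # axis ratio (11/7.5), absorbed into a safety factor of 2
        gap = np.abs(1.0 - m) * np.maximum(r, min(outer))
        near |= gap < 2.0 * (margin + t)
        if self.cut_axis is not None:
            s = self.cut_sign * q[:, _AXIS_INDEX[self.cut_axis]]
            near |= np.abs(s - self.planar_cut_outer) < margin + t
        return near

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "centre_um": list(self.centre),
            "semi_axes_um": list(self.semi_axes),
            "nucleus_radius_um": self.nucleus_radius,
            "membrane_thickness_um": self.membrane_thickness,
            "cut_axis": self.cut_axis,
            "cut_sign": self.cut_sign,
            "planar_cut_outer_um": self.planar_cut_outer,
            "planar_cut_inner_um": self.planar_cut_inner,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellModel":
        return cls(
            centre=tuple(d.get("centre_um", (0.0, 0.0, 0.0))),
            semi_axes=tuple(d.get("semi_axes_um", (7.5, 7.5, 11.0))),
            nucleus_radius=d.get("nucleus_radius_um", 5.0),
            membrane_thickness=d.get("membrane_thickness_um", 0.02),
            cut_axis=d.get("cut_axis"),
            cut_sign=d.get("cut_sign", 1),
            planar_cut_outer=d.get("planar_cut_outer_um"),
            planar_cut_inner=d.get("planar_cut_inner_um"),
        )


def classify_point(p, cell: CellModel) -> Compartment:
    """Classify a single 3-D point (µm) into a compartment."""
    return Compartment(int(cell.classify(np.asarray(p, dtype=float)[None, :])[0]))


@dataclass(frozen=True)
class MultiCellLayout:
    """A primary cell plus one adjacent cell along X or Z.

    Compartment queries return ``(cell_id, compartment)`` with cell_id 0 for
    the primary cell, 1 for the adjacent cell and -1 for points in neither.
    The primary cell takes precedence on the (measure-zero) shared face of a
    compressed pair.
    """

    primary: CellModel
    adjacent: CellModel
    axis: str = "z"
    mode: str = "compressed"
    centre_separation: float = 12.2

    def classify(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cp = self.primary.classify(points)
        ca = self.adjacent.classify(points)
        in_p = cp != int(Compartment.EXTRACELLULAR)
        in_a = (~in_p) & (ca != int(Compartment.EXTRACELLULAR))
        cell_id = np.full(len(cp), -1, dtype=np.int8)
        cell_id[in_p] = 0
        cell_id[in_a] = 1
        comp = np.full(len(cp), int(Compartment.EXTRACELLULAR), dtype=np.int8)
        comp[in_p] = cp[in_p]
        comp[in_a] = ca[in_a]
        return cell_id, comp

    @property
    def cells(self) -> tuple[CellModel, CellModel]:
        return (self.primary, self.adjacent)

    def near_membrane(self, points: np.ndarray, margin: float) -> np.ndarray:
        return self.primary.near_membrane(points, margin) | self.adjacent.near_membrane(
            points, margin
        )

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "mode": self.mode,
            "centre_separation_um": self.centre_separation,
            "primary": self.primary.to_dict(),
            "adjacent": self.adjacent.to_dict(),
        }


def build_layout(
    mode: str,
    axis: str = "z",
    gap: float = 1.0,
    cell: CellModel | None = None,
    cut_outer: float = 6.1,
    cut_inner: float = 6.08,
) -> MultiCellLayout:
    """Construct a two-cell layout.

    ``compressed`` applies planar cuts at 6.1 µm (cell boundary) and 6.08 µm
    (cytoplasm boundary) from the nucleus centre on the facing side of each
    cell, giving a centre separation of 12.2 µm with the flat 20 nm membrane
    slabs of the two cells coincident.  ``touching`` places the uncut cells
    with membranes in contact (22 µm separation along Z, 15 µm along X);
    ``separated`` adds ``gap`` µm (default 1 µm) of extracellular water.
    """
    base = cell if cell is not None else CellModel()
    if axis not in ("x", "z"):
        raise GeometryError("axis must be 'x' (beam-perpendicular) or 'z' (beam-parallel)")
    if mode not in ("compressed", "touching", "separated"):
        raise GeometryError(f"unknown layout mode {mode!r}")
    ax = _AXIS_INDEX[axis]

    if mode == "compressed":
        if cut_inner < base.nucleus_radius + base.membrane_thickness:
            raise GeometryError("compressed cut would intersect the nucleus")
        sep = 2.0 * cut_outer
        primary = replace(
            base,
            cut_axis=axis,
            cut_sign=1,
            planar_cut_outer=cut_outer,
            planar_cut_inner=cut_inner,
        )
        adj_centre = list(base.centre)
        adj_centre[ax] += sep
        adjacent = replace(
            primary,
            centre=tuple(adj_centre),
            cut_sign=-1,
        )
        return MultiCellLayout(primary, adjacent, axis, mode, sep)

    touch_sep = 2.0 * base.semi_axes[ax]
    if mode == "touching":
        sep = touch_sep
    else:
        if gap < 0:
            raise GeometryError("gap must be non-negative")
        sep = touch_sep + gap
    adj_centre = list(base.centre)
    adj_centre[ax] += sep
    adjacent = replace(base, centre=tuple(adj_centre))
    return MultiCellLayout(base, adjacent, axis, mode, sep)


def compartment_volume(
    cell: CellModel,
    compartment: Compartment | str,
    n_samples: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Volume of a compartment in µm³ with its standard error.

    Monte Carlo over the outer bounding box; exact closed forms (zero
    standard error) are returned for the uncut nucleus sphere and for the
    whole outer ellipsoid (``compartment="cell"``).  The extracellular
    region is unbounded and therefore rejected.
    """
    if n_samples < 1:
        raise GeometryError("n_samples must be >= 1")
    if compartment == "cell":
        if cell.cut_axis is None:
            return cell.outer_volume(), 0.0
        target = None  # cut cell: MC over everything inside the outer boundary
    else:
        compartment = Compartment(compartment)
        if compartment == Compartment.EXTRACELLULAR:
            raise GeometryError("extracellular volume is unbounded")
        if compartment == Compartment.NUCLEUS:
            return cell.nucleus_volume(), 0.0
        target = int(compartment)

    rng = np.random.default_rng(seed)
    lo = np.asarray(cell.centre) - np.asarray(cell.semi_axes)
    hi = np.asarray(cell.centre) + np.asarray(cell.semi_axes)
    box = float(np.prod(hi - lo))
    hits = 0
    remaining = int(n_samples)
    chunk = 500_000
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(m, 3))
        labels = cell.classify(pts)
        if target is None:
            hits += int(np.count_nonzero(labels != int(Compartment.EXTRACELLULAR)))
        else:
            hits += int(np.count_nonzero(labels == target))
        remaining -= m
    p = hits / n_samples
    vol = p * box
    se = box * np.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
    if vol == 0.0:
        return 0.0, se
    return vol, se
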