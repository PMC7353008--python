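"""Aggregation of transport and chemistry outputs into per-proton scores.

A :class:`ScoreSet` holds, per cell and compartment, the secondary-electron
dose (eV per incident proton) and the reactive-species yield over time
(count per incident proton), optionally with a voxel grid of species
positions at the end of the chemistry stage.  Per-proton normalisation
makes scores additive over disjoint proton batches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import SpeciesPopulation, Status
from .geometry import CellModel, Compartment, MultiCellLayout
from .transport import Deposits, compartment_dose

__all__ = ["ScoreSet", "ScoringError", "score_run", "adjacent_cell_yields"]


class ScoringError(RuntimeError):
    pass


@dataclass
class ScoreSet:
    """Per-proton, per-compartment dose and yield for one run."""

    dose: pd.DataFrame  # cell_id, compartment, ev_per_proton
    yields: pd.DataFrame  # t_s, cell_id, compartment, count_per_proton
    n_protons: int
    status_totals: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    voxel_grid: np.ndarray | None = None
    voxel_origin: np.ndarray | None = None
    voxel_spacing: float | None = None

    @property
    def t_end(self) -> float:
        return float(self.yields["t_s"].max())

    def yield_at_end(self, cell_id: int, compartment: str) -> float:
        sel = self.yields[
            (self.yields["t_s"] == self.t_end)
            & (self.yields["cell_id"] == cell_id)
            & (self.yields["compartment"] == compartment)
        ]
        return float(sel["count_per_proton"].sum())

    def dose_of(self, cell_id: int, compartment: str) -> float:
        sel = self.dose[
            (self.dose["cell_id"] == cell_id)
            & (self.dose["compartment"] == compartment)
        ]
        return float(sel["ev_per_proton"].sum())

    def to_csv(self, path) -> None:
        """Summary CSV: one row per cell/compartment/time plus dose rows."""
        y = self.yields.copy()
        y["quantity"] = "yield_per_proton"
        y = y.rename(columns={"count_per_proton": "value"})
        d = self.dose.copy()
        d["t_s"] = np.nan
        d["quantity"] = "dose_ev_per_proton"
        d = d.rename(columns={"ev_per_proton": "value"})
        cols = ["quantity", "t_s", "cell_id", "compartment", "value"]
        pd.concat([d[cols], y[cols]]).to_csv(path, index=False, float_format="%.10g")

    def save_voxel_grid(self, path_prefix: str) -> None:
        """Raw 3-D array (.npy) plus a JSON header with origin (µm),
        spacing (µm) and axis order."""
        if self.voxel_grid is None:
            raise ScoringError("run was scored without a voxel grid")
        np.save(path_prefix + ".npy", self.voxel_grid)
        with open(path_prefix + ".json", "w") as fh:
            json.dump(
                {
                    "origin_um": list(map(float, self.voxel_origin)),
                    "spacing_um": self.voxel_spacing,
                    "axis_order": "x,y,z",
                    "shape": list(self.voxel_grid.shape),
                },
                fh,
                indent=2,
            )

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n_protons": self.n_protons, "provenance": self.provenance},
                fh,
                indent=2,
                sort_keys=True,
            )


def score_run(
    deposits: Deposits,
    pop: SpeciesPopulation,
    timeseries: pd.DataFrame,
    geom: CellModel | MultiCellLayout,
    n_protons: int,
    voxel_spacing_um: float | None = None,
    box_half_um: float = 12.5,
    provenance: dict | None = None,
) -> ScoreSet:
    """Combine one run's deposits and chemistry output into a ScoreSet."""
    if deposits.n and int(deposits.proton_id.max()) >= n_protons:
        raise ScoringError("deposit proton ids exceed the declared proton count")
    if deposits.n_protons != n_protons:
        raise ScoringError("mismatched proton counts between stages")

    dose = compartment_dose(deposits, geom)
    yields = timeseries.copy()
    yields["count_per_proton"] = yields["count"] / n_protons
    yields = yields.drop(columns=["count"])

    grid = origin = spacing = None
    if voxel_spacing_um is not None:
        alive = pop.positions[pop.status == int(Status.ALIVE)]
        edges = np.arange(-box_half_um, box_half_um + voxel_spacing_um / 2, voxel_spacing_um)
        grid, _ = np.histogramdd(alive, bins=(edges, edges, edges))
        grid = grid.astype(np.int32)
        origin = np.full(3, -box_half_um)
        spacing = voxel_spacing_um

    return ScoreSet(
        dose=dose,
        yields=yields,
        n_protons=n_protons,
        status_totals=pop.status_counts(),
        provenance=provenance or {},
        voxel_grid=grid,
        voxel_origin=origin,
        voxel_spacing=spacing,
    )


def adjacent_cell_yields(score: ScoreSet) -> dict[str, float]:
    """Ratios Y_adjacent / Y_primary at the final chemistry time.

    Returns {"nucleus": ..., "cytoplasm": ...}.  Raises
    :class:`ScoringError` for single-cell runs or a zero primary yield.
    """
    if 1 not in set(score.yields["cell_id"].unique()):
        raise ScoringError("adjacent-cell ratios need a two-cell layout run")
    out = {}
    for comp in ("nucleus", "cytoplasm"):
        y_prim = score.yield_at_end(0, comp)
        y_adj = score.yield_at_end(1, comp)
        if y_prim <= 0:
            raise ScoringError(f"zero primary {comp} yield: ratio undefined")
        out[comp] = y_adj / y_prim
    return out
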