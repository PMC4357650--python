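"""The DIPPS statistic, selection heuristics, and spatial maps.

DIPPS (difference in proportions of occurrence) contrasts, for each peak
group, the proportion of enzyme-treated spectra exhibiting the group with
the proportion of buffer-control spectra doing so::

    DIPPS = p_treated - p_control          in [-1, 1]

A value near 1 marks an analyte present throughout the treated region and
absent from control — the signature expected of an enzymatically released
N-glycan.  Groups are ranked by descending DIPPS (ties broken by
ascending AWM m/z for determinism).

Selection of "high-DIPPS" groups is either user-driven (top N) or
data-dependent: the heuristic implemented here scans every observed DIPPS
value as a candidate cutoff and keeps the cutoff whose DIPPS map has the
largest per-group occupancy contrast between the treated and control
masks.  The original heuristic it stands in for is unpublished, so this
is one admissible data-dependent rule, not a reproduction.

A DIPPS map counts, per spot, how many of the selected groups exhibit at
least one peak in that spot's spectrum.  Log ion-intensity maps use
log1p so spots without signal stay at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grouping import PeakGroup
from .io import ImagingDataset

__all__ = [
    "SpatialMap",
    "dipps_table",
    "rank_dipps",
    "select_top_n",
    "select_heuristic",
    "presence_matrix",
    "dipps_map",
    "log_intensity_map",
]


@dataclass
class SpatialMap:
    """A per-spot scalar field on the acquisition grid.

    ``values`` has shape (ny, nx) with NaN at unacquired positions;
    ``mask`` is True where a spot was acquired.
    """

    values: np.ndarray
    mask: np.ndarray

    @classmethod
    def from_spot_values(
        cls, dataset: ImagingDataset, spot_values: dict[str, float]
    ) -> "SpatialMap":
        ny, nx = dataset.grid_shape
        values = np.full((ny, nx), np.nan)
        mask = np.zeros((ny, nx), dtype=bool)
        for spot in dataset.spots:
            mask[spot.y, spot.x] = True
            values[spot.y, spot.x] = spot_values.get(spot.spot_id, 0.0)
        return cls(values, mask)

    def mean_inside(self, region_mask: np.ndarray) -> float:
        """Mean value over acquired spots inside a boolean mask."""
        sel = self.mask & region_mask
        if not sel.any():
            raise ValueError("mask covers no acquired spots")
        return float(np.nanmean(self.values[sel]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)

    def save_png(self, path, cmap: str = "viridis") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        im = ax.imshow(self.values, cmap=cmap, interpolation="nearest")
        fig.colorbar(im, ax=ax)
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        fig.savefig(path, dpi=150)
        plt.close(fig)


def dipps_table(occurrence: pd.DataFrame) -> pd.DataFrame:
    """Add ``dipps`` and ``rank`` columns to an occurrence table.

    Requires non-empty treated and control regions (NaN proportions raise).
    Rank 1 is the highest DIPPS; ties are broken by ascending AWM m/z.
    """
    if occurrence["p_treated"].isna().any() or occurrence["p_control"].isna().any():
        raise ValueError(
            "DIPPS undefined: treated or control region is empty"
        )
    out = occurrence.copy()
    out["dipps"] = out["p_treated"] - out["p_control"]
    order = np.lexsort((out["awm_mz"].values, -out["dipps"].values))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out


def rank_dipps(table: pd.DataFrame) -> pd.DataFrame:
    """The table sorted by rank (descending DIPPS, ascending AWM on ties)."""
    return table.sort_values("rank").reset_index(drop=True)


def select_top_n(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """The ``n`` highest-DIPPS groups (user-selected, data-independent)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rank_dipps(table).head(n).reset_index(drop=True)


def presence_matrix(
    groups: list[PeakGroup], dataset: ImagingDataset
) -> pd.DataFrame:
    """Boolean spots x groups indicator: spot exhibits >=1 peak of the group."""
    ids = dataset.spot_ids
    index = {sid: i for i, sid in enumerate(ids)}
    mat = np.zeros((len(ids), len(groups)), dtype=bool)
    for j, g in enumerate(groups):
        for sid in g.occupied_spots():
            mat[index[sid], j] = True
    return pd.DataFrame(mat, index=ids, columns=[g.group_id for g in groups])


def select_heuristic(
    table: pd.DataFrame,
    groups: list[PeakGroup],
    dataset: ImagingDataset,
) -> tuple[pd.DataFrame, float]:
    """Data-dependent DIPPS cutoff by occupancy-contrast maximisation.

    Every observed DIPPS value is a candidate cutoff ``c``.  For each,
    the groups with DIPPS >= c define a DIPPS map, scored by

        s(c) = mean count in treated spots / n_selected
             - mean count in control spots / n_selected

    i.e. the average per-group occupancy contrast between the regions.
    The cutoff maximising s is returned; ties prefer the larger cutoff
    (fewer groups).  Returns (selected sub-table ranked, cutoff).
    """
    if len(table) == 0:
        raise ValueError("no DIPPS results to select from")
    by_id = {g.group_id: g for g in groups}
    missing = set(table["group_id"]) - set(by_id)
    if missing:
        raise ValueError(f"groups absent from group list: {sorted(missing)[:5]}")
    sub_groups = [by_id[gid] for gid in table["group_id"]]
    pres = presence_matrix(sub_groups, dataset).values
    regions = np.array([s.region for s in dataset.spots])
    treated = regions == "treated"
    control = regions == "control"
    if not treated.any() or not control.any():
        raise ValueError("heuristic selection needs both treated and control spots")

    dipps = table["dipps"].values
    best_score, best_cut = -np.inf, None
    for c in np.unique(dipps):
        sel = dipps >= c
        n_sel = int(sel.sum())
        counts = pres[:, sel].sum(axis=1)
        score = (
            counts[treated].mean() / n_sel - counts[control].mean() / n_sel
        )
        # strictly-greater on the score plus ascending cutoff scan ensures
        # ties resolve to the largest cutoff
        if score >= best_score:
            best_score, best_cut = score, float(c)
    selected = rank_dipps(table[table["dipps"] >= best_cut])
    return selected.reset_index(drop=True), best_cut


def dipps_map(
    selected_groups: list[PeakGroup], dataset: ImagingDataset
) -> SpatialMap:
    """Per-spot count of selected groups exhibiting a peak at that spot."""
    if not selected_groups:
        raise ValueError("selection is empty")
    counts: dict[str, float] = {sid: 0.0 for sid in dataset.spot_ids}
    for g in selected_groups:
        for sid in g.occupied_spots():
            counts[sid] += 1.0
    return SpatialMap.from_spot_values(dataset, counts)


def log_intensity_map(group: PeakGroup, dataset: ImagingDataset) -> SpatialMap:
    """Per-spot log1p of the group's summed member-peak intensity."""
    values = {
        sid: float(np.log1p(v)) for sid, v in group.spot_intensity().items()
    }
    return SpatialMap.from_spot_values(dataset, values)
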