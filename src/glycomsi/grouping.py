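"""Peak grouping across spots and occurrence-based candidate filtering.

Peaks from all spectra are pooled and clustered along the m/z axis by
single linkage with a fixed linkage distance (default 0.1 m/z): sorted
peaks are cut wherever the gap between consecutive m/z values exceeds the
linkage distance, so each group is a maximal chain.  Every peak belongs
to exactly one group.

Each group gets an abundance-weighted mean (AWM) m/z, weighted by per-peak
S/N, and per-region occurrence counts.  Occurrence counts *spots*: a spot
contributes at most once to a group however many of its peaks fall in it,
which keeps occurrence proportions bounded by 1.

Two filters from the glycan-discovery workflow are provided:

* ``profiling_candidates`` — groups present in at least ``min_treated``
  enzyme-treated spots, at most ``max_control`` buffer-control spots, and
  above an m/z floor (defaults >= 2, <= 1, > 1000), with an optional more
  conservative treated-count threshold (>= 4);
* ``min_occurrence_filter`` — imaging-scale screen keeping groups that
  occur in at least ``min_spectra`` spectra overall (default 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImagingDataset

__all__ = [
    "PeakGroup",
    "group_peaks",
    "occurrence_table",
    "profiling_candidates",
    "min_occurrence_filter",
    "subset_groups",
]


@dataclass
class PeakGroup:
    """A cluster of peaks across spots, with its S/N-weighted mean m/z."""

    group_id: int
    spot_ids: np.ndarray  # object array of str, one per member peak
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    #: True when all member S/N are zero and the AWM fell back to the
    #: unweighted mean.
    awm_unweighted: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.mz.size == 0:
            raise ValueError("peak group cannot be empty")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def awm(self) -> float:
        """Abundance-weighted mean m/z, S/N as weights.

        Falls back to the unweighted mean (and flags ``awm_unweighted``)
        when every member S/N is zero.
        """
        total = self.snr.sum()
        if total > 0:
            return float(np.dot(self.mz, self.snr) / total)
        object.__setattr__(self, "awm_unweighted", True)
        return float(self.mz.mean())

    @property
    def mz_span(self) -> tuple[float, float]:
        return float(self.mz.min()), float(self.mz.max())

    def occupied_spots(self) -> set[str]:
        return set(self.spot_ids.tolist())

    def spot_intensity(self) -> dict[str, float]:
        """Summed member-peak intensity per spot."""
        out: dict[str, float] = {}
        for sid, inten in zip(self.spot_ids, self.intensity):
            out[sid] = out.get(sid, 0.0) + float(inten)
        return out


def group_peaks(dataset: ImagingDataset, linkage: float = 0.1) -> list[PeakGroup]:
    """Single-linkage 1-D clustering of all peaks along the m/z axis.

    Pools every peak in the dataset, sorts by m/z, and cuts at consecutive
    gaps strictly greater than ``linkage``.  Returns groups ordered by
    AWM m/z; an empty dataset yields an empty list.
    """
    if linkage <= 0:
        raise ValueError("linkage distance must be positive")
    spot_col, mz_col, int_col, snr_col = [], [], [], []
    for sid in dataset.spot_ids:
        peaks = dataset.peaklists[sid]
        if len(peaks) == 0:
            continue
        spot_col.append(np.full(len(peaks), sid, dtype=object))
        mz_col.append(peaks.mz)
        int_col.append(peaks.intensity)
        snr_col.append(peaks.snr)
    if not mz_col:
        return []
    spots = np.concatenate(spot_col)
    mz = np.concatenate(mz_col)
    intensity = np.concatenate(int_col)
    snr = np.concatenate(snr_col)
    order = np.argsort(mz, kind="stable")
    spots, mz, intensity, snr = spots[order], mz[order], intensity[order], snr[order]

    cuts = np.flatnonzero(np.diff(mz) > linkage) + 1
    starts = np.concatenate([[0], cuts])
    stops = np.concatenate([cuts, [mz.size]])
    groups = [
        PeakGroup(0, spots[a:b], mz[a:b], intensity[a:b], snr[a:b])
        for a, b in zip(starts, stops)
    ]
    groups.sort(key=lambda g: g.awm)
    for i, g in enumerate(groups):
        g.group_id = i
    return groups


def occurrence_table(
    groups: list[PeakGroup], dataset: ImagingDataset
) -> pd.DataFrame:
    """Per-group, per-region spot-occurrence counts and proportions.

    Columns: ``group_id, awm_mz, n_peaks, n_treated, n_control, n_spots,
    p_treated, p_control``.  ``n_spots`` is the number of distinct spots
    (any region) exhibiting the group.  Proportions divide by the region
    size and are NaN (missing) when the region is empty.
    """
    region_of = {s.spot_id: s.region for s in dataset.spots}
    sizes = dataset.region_sizes()
    rows = []
    for g in groups:
        spots = g.occupied_spots()
        n_t = sum(1 for s in spots if region_of[s] == "treated")
        n_c = sum(1 for s in spots if region_of[s] == "control")
        rows.append(
            {
                "group_id": g.group_id,
                "awm_mz": g.awm,
                "n_peaks": g.n_peaks,
                "n_treated": n_t,
                "n_control": n_c,
                "n_spots": len(spots),
                "p_treated": n_t / sizes["treated"] if sizes["treated"] else np.nan,
                "p_control": n_c / sizes["control"] if sizes["control"] else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_id", "awm_mz", "n_peaks", "n_treated", "n_control",
            "n_spots", "p_treated", "p_control",
        ],
    )


def profiling_candidates(
    table: pd.DataFrame,
    min_treated: int = 2,
    max_control: int = 1,
    min_mz: float = 1000.0,
    conservative_min_treated: int | None = None,
) -> pd.DataFrame:
    """Occurrence-based N-glycan candidate filter (inclusive thresholds).

    Keeps groups with treated count >= ``min_treated``, control count
    <= ``max_control`` and AWM m/z strictly above ``min_mz``.  Passing
    ``conservative_min_treated`` (e.g. 4) raises the treated threshold
    for a more conservative candidate list.
    """
    if min_treated < 0 or max_control < 0:
        raise ValueError("thresholds must be non-negative")
    thr = conservative_min_treated if conservative_min_treated is not None else min_treated
    keep = (
        (table["n_treated"] >= thr)
        & (table["n_control"] <= max_control)
        & (table["awm_mz"] > min_mz)
    )
    return table[keep].reset_index(drop=True)


def min_occurrence_filter(
    table: pd.DataFrame, min_spectra: int = 100
) -> pd.DataFrame:
    """Keep groups occurring in at least ``min_spectra`` spectra overall."""
    if min_spectra < 1:
        raise ValueError("min_spectra must be >= 1")
    return table[table["n_spots"] >= min_spectra].reset_index(drop=True)


def subset_groups(
    groups: list[PeakGroup], table: pd.DataFrame
) -> list[PeakGroup]:
    """The PeakGroup objects whose ids appear in a (filtered) table."""
    wanted = set(table["group_id"].tolist())
    return [g for g in groups if g.group_id in wanted]
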