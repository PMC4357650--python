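"""Containers and plain-text IO for spatially referenced peak-list data.

A dataset is a rectangular acquisition grid of spots; each spot carries a
centroided peak list (m/z, intensity, S/N) and a region label from the
closed vocabulary {treated, control, calibrant, none}.  The on-disk
layout is a manifest CSV (``spot_id,x,y,region,file``) plus one
tab-separated peak list per spot (``mz<TAB>intensity<TAB>snr``).  Raw
(profile-mode) spectra use a two-column ``mz<TAB>intensity`` TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "ParseError",
    "SpotMeta",
    "PeakList",
    "RawProfile",
    "ImagingDataset",
    "read_dataset",
    "write_dataset",
    "read_peaklist",
    "write_peaklist",
]

REGIONS = ("treated", "control", "calibrant", "none")


class ParseError(ValueError):
    """A malformed manifest or peak-list file; message names file and line."""


@dataclass(frozen=True)
class SpotMeta:
    """One acquisition position: unique id, 0-based grid coords, region label.

    x increases rightward, y downward.
    """

    spot_id: str
    x: int
    y: int
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(
                f"spot {self.spot_id!r}: region {self.region!r} not in {REGIONS}"
            )
        if self.x < 0 or self.y < 0:
            raise ValueError(f"spot {self.spot_id!r}: negative grid coordinate")


class PeakList:
    """Centroided peaks of one spectrum, sorted ascending by m/z."""

    __slots__ = ("mz", "intensity", "snr")

    def __init__(self, mz, intensity, snr) -> None:
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        snr = np.asarray(snr, dtype=float)
        if not (mz.shape == intensity.shape == snr.shape) or mz.ndim != 1:
            raise ValueError("mz, intensity and snr must be 1-D and equal length")
        if np.isnan(mz).any() or np.isnan(intensity).any() or np.isnan(snr).any():
            raise ValueError("peak list contains NaN")
        if (intensity < 0).any() or (snr < 0).any():
            raise ValueError("intensity and snr must be non-negative")
        order = np.argsort(mz, kind="stable")
        self.mz = mz[order]
        self.intensity = intensity[order]
        self.snr = snr[order]

    def __len__(self) -> int:
        return self.mz.size

    def filter_range(self, lo: float, hi: float) -> "PeakList":
        """Peaks with lo <= m/z < hi."""
        keep = (self.mz >= lo) & (self.mz < hi)
        return PeakList(self.mz[keep], self.intensity[keep], self.snr[keep])

    def with_mz(self, new_mz) -> "PeakList":
        return PeakList(new_mz, self.intensity.copy(), self.snr.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakList)
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
            and np.array_equal(self.snr, other.snr)
        )


@dataclass
class RawProfile:
    """A profile-mode spectrum: strictly increasing m/z axis + intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D and equal length")
        if self.mz.size >= 2 and not (np.diff(self.mz) > 0).all():
            raise ValueError("m/z axis must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class ImagingDataset:
    """Spots, their peak lists, optional raw profiles and the m/z range."""

    spots: list[SpotMeta]
    peaklists: dict[str, PeakList]
    raw_profiles: dict[str, RawProfile] | None = None
    mz_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate spot ids: {dup}")
        coords = [(s.x, s.y) for s in self.spots]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate grid coordinates")
        missing = [i for i in ids if i not in self.peaklists]
        if missing:
            raise ValueError(f"spots without peak list: {missing[:5]}")

    # -- convenience accessors ------------------------------------------

    @property
    def spot_ids(self) -> list[str]:
        return [s.spot_id for s in self.spots]

    def region_spot_ids(self, region: str) -> list[str]:
        return [s.spot_id for s in self.spots if s.region == region]

    def region_sizes(self) -> dict[str, int]:
        sizes = {r: 0 for r in REGIONS}
        for s in self.spots:
            sizes[s.region] += 1
        return sizes

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(ny, nx): smallest grid containing all spot coordinates."""
        if not self.spots:
            return (0, 0)
        return (
            max(s.y for s in self.spots) + 1,
            max(s.x for s in self.spots) + 1,
        )

    def spot_coords(self) -> dict[str, tuple[int, int]]:
        return {s.spot_id: (s.x, s.y) for s in self.spots}

    def total_peaks(self) -> int:
        return sum(len(p) for p in self.peaklists.values())

    def map_peaklists(self, fn) -> "ImagingDataset":
        """New dataset with ``fn`` applied to every peak list."""
        return replace(
            self, peaklists={k: fn(v) for k, v in self.peaklists.items()}
        )


# ---------------------------------------------------------------------------
# Plain-text readers / writers


def read_peaklist(path) -> PeakList:
    """Read one ``mz<TAB>intensity<TAB>snr`` TSV; peaks are sorted on load."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("mz", "intensity", "snr"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r} (line 1)")
    bad = df[df[["mz", "intensity", "snr"]].isna().any(axis=1)]
    if len(bad):
        # +2: 1-based lines, header on line 1
        raise ParseError(f"{path}: malformed row at line {bad.index[0] + 2}")
    return PeakList(df["mz"].values, df["intensity"].values, df["snr"].values)


def write_peaklist(peaks: PeakList, path) -> None:
    pd.DataFrame(
        {"mz": peaks.mz, "intensity": peaks.intensity, "snr": peaks.snr}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_dataset(
    manifest_path,
    peaklist_dir=None,
    mz_range: tuple[float, float] | None = None,
) -> ImagingDataset:
    """Load a dataset from a manifest CSV and its referenced peak-list files.

    ``peaklist_dir`` defaults to the manifest's directory.  When
    ``mz_range`` is given it acts as an acquisition-range filter: peaks
    outside [lo, hi) are dropped on read (the MALDI-TOF acquisition window
    and matrix-suppression cutoff are modelled this way).
    """
    manifest_path = Path(manifest_path)
    base = Path(peaklist_dir) if peaklist_dir is not None else manifest_path.parent
    try:
        mf = pd.read_csv(manifest_path, dtype={"spot_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"{manifest_path}: {exc}") from exc
    required = ["spot_id", "x", "y", "region", "file"]
    missing = [c for c in required if c not in mf.columns]
    if missing:
        raise ParseError(f"{manifest_path}: missing columns {missing} (line 1)")

    spots: list[SpotMeta] = []
    peaklists: dict[str, PeakList] = {}
    seen: set[str] = set()
    for i, row in mf.iterrows():
        line = i + 2
        sid = str(row["spot_id"])
        if sid in seen:
            raise ParseError(f"{manifest_path}: duplicate spot id {sid!r} at line {line}")
        seen.add(sid)
        try:
            spot = SpotMeta(sid, int(row["x"]), int(row["y"]), str(row["region"]))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{manifest_path}: line {line}: {exc}") from exc
        fpath = base / str(row["file"])
        if not fpath.exists():
            raise ParseError(
                f"{manifest_path}: line {line}: peak list file not found: {fpath}"
            )
        peaks = read_peaklist(fpath)
        if mz_range is not None:
            peaks = peaks.filter_range(*mz_range)
        spots.append(spot)
        peaklists[sid] = peaks
    return ImagingDataset(spots, peaklists, mz_range=mz_range)


def write_dataset(dataset: ImagingDataset, outdir) -> Path:
    """Write manifest + per-spot peak-list TSVs; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    rows = []
    for spot in dataset.spots:
        fname = f"peaks/{spot.spot_id}.tsv"
        write_peaklist(dataset.peaklists[spot.spot_id], outdir / fname)
        rows.append(
            {"spot_id": spot.spot_id, "x": spot.x, "y": spot.y,
             "region": spot.region, "file": fname}
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
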