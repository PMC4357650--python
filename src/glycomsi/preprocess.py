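"""Spectrum preprocessing: baseline, normalisation, reduction, recalibration, binning.

These are the generic steps that sit between raw peak lists and the
feature-extraction stages: morphological (TopHat) baseline subtraction,
TIC and RMS normalisation, peak-preserving data reduction, quadratic
internal mass recalibration against a calibrant list, and fixed-width
binning of peak lists into a spot x m/z-bin intensity matrix.

Row-wise TIC/RMS normalisation is also exposed as sklearn-style
transformers so the binned matrix can be fed through a Pipeline into the
multivariate stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ImagingDataset, PeakList, RawProfile

__all__ = [
    "tophat_baseline",
    "normalize_tic",
    "normalize_rms",
    "reduce_profile",
    "CalibrationModel",
    "fit_recalibration",
    "apply_recalibration",
    "BinnedMatrix",
    "bin_spectra",
    "occupancy_filter",
    "TicNormalizer",
    "RmsNormalizer",
]


def tophat_baseline(profile: RawProfile, window: int = 101) -> RawProfile:
    """Subtract the morphological opening of the intensity trace.

    The opening (grayscale erosion then dilation with a flat structuring
    element of ``window`` points) tracks the baseline under the peaks; the
    residual is non-negative by construction.  ``window`` must be odd, at
    least 3, and smaller than the profile length; edges are handled by
    replicating the boundary samples.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window >= len(profile):
        raise ValueError(
            f"window {window} must be smaller than profile length {len(profile)}"
        )
    opened = ndimage.grey_opening(profile.intensity, size=window, mode="nearest")
    residual = profile.intensity - opened
    # opening <= signal pointwise, so the residual is >= 0 up to float error
    return RawProfile(profile.mz, np.maximum(residual, 0.0))


def _normalized_intensities(intensity: np.ndarray, how: str) -> np.ndarray:
    if how == "tic":
        total = intensity.sum()
        if total <= 0:
            raise ValueError("cannot TIC-normalize an all-zero spectrum")
        return intensity / total
    if how == "rms":
        rms = np.sqrt(np.mean(np.square(intensity)))
        if rms <= 0:
            raise ValueError("cannot RMS-normalize an all-zero spectrum")
        return intensity / rms
    raise ValueError(how)


def _normalize(spectrum, how: str):
    if isinstance(spectrum, PeakList):
        return PeakList(
            spectrum.mz,
            _normalized_intensities(spectrum.intensity, how),
            spectrum.snr,
        )
    if isinstance(spectrum, RawProfile):
        return RawProfile(spectrum.mz, _normalized_intensities(spectrum.intensity, how))
    raise TypeError(f"expected PeakList or RawProfile, got {type(spectrum)}")


def normalize_tic(spectrum):
    """Divide intensities by their sum (total ion current); output sums to 1."""
    return _normalize(spectrum, "tic")


def normalize_rms(spectrum):
    """Divide intensities by their root mean square; output RMS is 1."""
    return _normalize(spectrum, "rms")


def reduce_profile(profile: RawProfile, n_points: int) -> RawProfile:
    """Peak-preserving data reduction to at most ``n_points`` samples.

    The m/z span is divided into ``n_points`` equal half-open intervals
    (the last is closed) and each output sample takes the maximum
    intensity inside its interval, so peak apexes are never lost.  Output
    m/z nodes are the interval centres; empty intervals get intensity 0.
    Profiles already at or below ``n_points`` are returned unchanged.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(profile) <= n_points:
        return profile
    lo, hi = profile.mz[0], profile.mz[-1]
    edges = np.linspace(lo, hi, n_points + 1)
    idx = np.clip(np.searchsorted(edges, profile.mz, side="right") - 1, 0, n_points - 1)
    out = np.zeros(n_points)
    np.maximum.at(out, idx, profile.intensity)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RawProfile(centers, out)


# ---------------------------------------------------------------------------
# Quadratic internal recalibration


@dataclass(frozen=True)
class CalibrationModel:
    """corrected = a*m**2 + b*m + c, with ppm residuals at the calibrants."""

    a: float
    b: float
    c: float
    observed: np.ndarray
    reference: np.ndarray
    residuals_ppm: np.ndarray

    def __call__(self, mz):
        mz = np.asarray(mz, dtype=float)
        return self.a * mz * mz + self.b * mz + self.c

    @property
    def max_abs_residual_ppm(self) -> float:
        return float(np.max(np.abs(self.residuals_ppm))) if len(self.residuals_ppm) else 0.0

    def is_monotone(self, lo: float, hi: float) -> bool:
        """Strictly increasing over [lo, hi] (derivative 2am+b is linear)."""
        return (2 * self.a * lo + self.b) > 0 and (2 * self.a * hi + self.b) > 0


def _match_calibrants(observed, reference, tol_ppm):
    """Pair each reference mass with its nearest observed peak within tol."""
    observed = np.asarray(observed, dtype=float)
    obs, ref = [], []
    for r in np.asarray(reference, dtype=float):
        if observed.size == 0:
            break
        j = int(np.argmin(np.abs(observed - r)))
        if abs(observed[j] - r) / r * 1e6 <= tol_ppm:
            obs.append(observed[j])
            ref.append(r)
    return np.array(obs), np.array(ref)


def fit_recalibration(
    observed_mz,
    reference_mz,
    match_tol_ppm: float = 500.0,
) -> CalibrationModel:
    """Least-squares quadratic observed -> reference from matched calibrants.

    ``observed_mz`` may be a full calibrant-spot peak list; each reference
    mass is matched to its nearest observed peak within ``match_tol_ppm``.
    At least three matched pairs are required (a quadratic has three
    coefficients); with exactly three the fit interpolates and residuals
    are zero.
    """
    obs, ref = _match_calibrants(observed_mz, reference_mz, match_tol_ppm)
    if len(obs) < 3:
        raise ValueError(
            f"need >=3 matched calibrant pairs within {match_tol_ppm} ppm, got {len(obs)}"
        )
    if len(np.unique(obs)) < len(obs):
        raise ValueError("degenerate calibrants: duplicate observed masses")
    a, b, c = np.polyfit(obs, ref, 2)
    fitted = a * obs * obs + b * obs + c
    residuals_ppm = (fitted - ref) / ref * 1e6
    return CalibrationModel(float(a), float(b), float(c), obs, ref, residuals_ppm)


def apply_recalibration(
    model: CalibrationModel,
    dataset: ImagingDataset,
    scope: list[str] | None = None,
) -> ImagingDataset:
    """Transform every peak m/z in ``scope`` (default: all spots).

    The model must be strictly increasing over the dataset's m/z range so
    peak ordering is preserved.
    """
    if dataset.mz_range is not None:
        lo, hi = dataset.mz_range
    else:
        all_mz = [p.mz for p in dataset.peaklists.values() if len(p)]
        if not all_mz:
            return dataset
        lo = min(float(m[0]) for m in all_mz)
        hi = max(float(m[-1]) for m in all_mz)
    if not model.is_monotone(lo, hi):
        raise ValueError(
            f"calibration model is not monotone over [{lo:.1f}, {hi:.1f}]"
        )
    scope_set = set(dataset.spot_ids if scope is None else scope)

    def recal(sid, peaks):
        if sid not in scope_set or len(peaks) == 0:
            return peaks
        return peaks.with_mz(model(peaks.mz))

    new_lists = {sid: recal(sid, pl) for sid, pl in dataset.peaklists.items()}
    return ImagingDataset(
        dataset.spots, new_lists, dataset.raw_profiles, dataset.mz_range
    )


# ---------------------------------------------------------------------------
# Binning


@dataclass
class BinnedMatrix:
    """Spot x m/z-bin summed-intensity matrix with half-open [lo, hi) bins."""

    spot_ids: list[str]
    bin_edges: np.ndarray
    intensities: np.ndarray  # shape (n_spots, n_bins)
    #: explicit bin centres; set when bins are no longer contiguous
    #: (after :func:`occupancy_filter`), otherwise derived from the edges.
    centers: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        if self.centers is not None:
            return self.centers
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.intensities,
            index=self.spot_ids,
            columns=np.round(self.bin_centers, 4),
        )


def bin_spectra(
    dataset: ImagingDataset,
    width: float = 0.5,
    mz_range: tuple[float, float] | None = None,
) -> BinnedMatrix:
    """Sum each spot's peak intensities into fixed-width half-open bins.

    A peak exactly on a bin edge belongs to the upper bin.  Total in-range
    intensity is conserved.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if mz_range is None:
        mz_range = dataset.mz_range
    if mz_range is None:
        mzs = [p.mz for p in dataset.peaklists.values() if len(p)]
        if not mzs:
            raise ValueError("empty dataset and no m/z range given")
        lo = min(float(m[0]) for m in mzs)
        hi = max(float(m[-1]) for m in mzs) + width
    else:
        lo, hi = mz_range
    if hi <= lo:
        raise ValueError("mz range upper bound must exceed lower bound")
    n_bins = int(np.ceil((hi - lo) / width))
    edges = lo + width * np.arange(n_bins + 1)
    matrix = np.zeros((len(dataset.spots), n_bins))
    for i, sid in enumerate(dataset.spot_ids):
        peaks = dataset.peaklists[sid]
        if len(peaks) == 0:
            continue
        keep = (peaks.mz >= lo) & (peaks.mz < edges[-1])
        idx = np.floor((peaks.mz[keep] - lo) / width).astype(int)
        np.add.at(matrix[i], idx, peaks.intensity[keep])
    return BinnedMatrix(list(dataset.spot_ids), edges, matrix)


def occupancy_filter(binned: BinnedMatrix, min_spectra: int = 100) -> BinnedMatrix:
    """Data reduction: keep only bins occupied in at least ``min_spectra`` spectra.

    The same occurrence screen applied to peak groups before DIPPS; on a
    binned matrix it removes sparsely populated noise bins ahead of the
    multivariate stages.  Bin edges of dropped bins are removed, so the
    surviving columns keep their centre m/z via ``bin_centers``.
    """
    if min_spectra < 1:
        raise ValueError("min_spectra must be >= 1")
    occupancy = (binned.intensities > 0).sum(axis=0)
    keep = occupancy >= min_spectra
    return BinnedMatrix(
        list(binned.spot_ids),
        binned.bin_edges,
        binned.intensities[:, keep],
        centers=binned.bin_centers[keep],
    )


# ---------------------------------------------------------------------------
# sklearn-style row normalizers


class TicNormalizer(BaseEstimator, TransformerMixin):
    """Row-wise total-ion-current normalisation of a spot x bin matrix.

    Each row is divided by its sum so rows sum to 1.  Rows summing to zero
    raise, mirroring :func:`normalize_tic`.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValueError("cannot TIC-normalize all-zero rows")
        return X / totals


class RmsNormalizer(BaseEstimator, TransformerMixin):
    """Row-wise root-mean-square normalisation of a spot x bin matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        rms = np.sqrt(np.mean(np.square(X), axis=1, keepdims=True))
        if (rms <= 0).any():
            raise ValueError("cannot RMS-normalize all-zero rows")
        return X / rms
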