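"""Ground-truthed phantom MALDI-imaging datasets of a two-region kidney section.

The phantom emulates the layout of an on-tissue PNGase F imaging
experiment on a kidney section: a rectangular acquisition grid holds an
enzyme-treated tissue (an elliptical section with a cortex annulus around
a medulla core), a buffer-control tissue of the same anatomy, and a pair
of calibrant spots carrying the GLY3 standard mixture.  Spots outside any
tissue are labelled ``none`` and contain only matrix noise.

For every spot and every planted glycan, presence is an independent
Bernoulli draw with a prevalence that depends on the sub-region
(treated cortex, treated medulla, control); a present glycan contributes
one peak at its sodiated m/z plus Gaussian jitter, with log-normal
intensity and S/N of at least 3 (mirroring the picker's S/N > 3
threshold).  Each spectrum additionally receives a Poisson number of
uniform noise peaks.  Everything is reproducible from the seed, and the
generator returns the ground truth (planted masses, prevalences, region
masks, expected DIPPS) alongside the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ImagingDataset, PeakList, SpotMeta
from .mass import (
    GLYCOSYLAMINE_SHIFT,
    GlycanComposition,
    gly3_standards,
    sodiated_mz,
)

__all__ = [
    "PlantedGlycan",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "make_gly3_calibrant_spots",
    "default_kidney_spec",
]


@dataclass(frozen=True)
class PlantedGlycan:
    """One glycan species planted in the phantom, with region prevalences."""

    name: str
    composition: GlycanComposition
    prevalence_cortex: float
    prevalence_medulla: float
    prevalence_control: float
    #: median peak intensity (log-normal location, in arbitrary counts)
    intensity_median: float = 400.0

    def __post_init__(self) -> None:
        for p in (
            self.prevalence_cortex,
            self.prevalence_medulla,
            self.prevalence_control,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: prevalence {p} outside [0, 1]")

    @property
    def sodiated_mz(self) -> float:
        return sodiated_mz(self.composition)


@dataclass
class PhantomSpec:
    """Geometry, planted species and noise model of a phantom dataset.

    The default geometry is a 60 x 40 grid.  The treated tissue is an
    ellipse centred at ``treated_center`` whose inner ellipse (half the
    semi-axes) is the medulla and whose remainder is the cortex; the
    control tissue is a second ellipse with the same anatomy but its own
    prevalences.  ``jitter_sigma`` should stay well below a quarter of the
    grouping linkage distance (0.1 m/z) so planted masses resolve into
    single groups.
    """

    nx: int = 60
    ny: int = 40
    treated_center: tuple[float, float] = (16.0, 20.0)
    treated_semiaxes: tuple[float, float] = (13.0, 16.0)
    control_center: tuple[float, float] = (45.0, 20.0)
    control_semiaxes: tuple[float, float] = (10.0, 12.0)
    medulla_fraction: float = 0.5
    calibrant_spots: tuple[tuple[int, int], ...] = ((1, 1), (3, 1))
    planted: list[PlantedGlycan] = field(default_factory=list)
    mz_range: tuple[float, float] = (1000.0, 3000.0)
    jitter_sigma: float = 0.02
    snr_floor: float = 3.0
    snr_scale: float = 10.0
    noise_snr_scale: float = 2.0
    noise_rate: float = 5.0
    intensity_log_sigma: float = 0.7
    noise_intensity_median: float = 50.0
    glycosylamine_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must be non-empty")
        if not 0.0 < self.medulla_fraction < 1.0:
            raise ValueError("medulla_fraction must be in (0, 1)")
        if self.jitter_sigma < 0 or self.noise_rate < 0:
            raise ValueError("jitter and noise rate must be non-negative")
        if not 0.0 <= self.glycosylamine_fraction <= 1.0:
            raise ValueError("glycosylamine_fraction must be in [0, 1]")
        lo, hi = self.mz_range
        if hi <= lo:
            raise ValueError("mz_range upper bound must exceed lower bound")

    # -- geometry -------------------------------------------------------

    def _ellipse_mask(self, center, semiaxes, shrink: float = 1.0) -> np.ndarray:
        cx, cy = center
        ax, ay = semiaxes[0] * shrink, semiaxes[1] * shrink
        y, x = np.mgrid[0 : self.ny, 0 : self.nx]
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0

    def masks(self) -> dict[str, np.ndarray]:
        """Boolean (ny, nx) masks: treated, cortex, medulla, control, calibrant."""
        treated = self._ellipse_mask(self.treated_center, self.treated_semiaxes)
        medulla = self._ellipse_mask(
            self.treated_center, self.treated_semiaxes, self.medulla_fraction
        )
        control = self._ellipse_mask(self.control_center, self.control_semiaxes)
        calibrant = np.zeros((self.ny, self.nx), dtype=bool)
        for x, y in self.calibrant_spots:
            calibrant[y, x] = True
        if (treated & control).any():
            raise ValueError("treated and control tissues overlap")
        if (calibrant & (treated | control)).any():
            raise ValueError("calibrant spots overlap a tissue region")
        return {
            "treated": treated,
            "cortex": treated & ~medulla,
            "medulla": treated & medulla,
            "control": control,
            "calibrant": calibrant,
        }


@dataclass
class PhantomTruth:
    """Generator ground truth: planted-mass table and region masks.

    ``table`` columns: name, sodiated_mz, the three sub-region
    prevalences, the area-weighted treated prevalence ``p_treated`` and
    ``expected_dipps = p_treated - prevalence_control``.
    """

    table: pd.DataFrame
    masks: dict[str, np.ndarray]

    def treated_specific(self, min_dipps: float = 0.2) -> pd.DataFrame:
        """Planted species whose expected DIPPS exceeds ``min_dipps``."""
        return self.table[self.table["expected_dipps"] > min_dipps].reset_index(
            drop=True
        )


def make_gly3_calibrant_spots(
    distortion: tuple[float, float, float] = (0.0, 1.0, 0.0),
    snr: float = 80.0,
    intensity: float = 5000.0,
) -> PeakList:
    """A calibrant-spot peak list: the GLY3 [M+Na]+ triplet, optionally distorted.

    ``distortion`` = (a, b, c) maps each true m/z ``m`` to ``a*m**2 + b*m + c``
    (must be monotone over the calibrant span); the identity leaves the
    peaks at the reference sodiated masses.  Round-tripping a planted
    distortion through ``fit_recalibration`` recovers it exactly.
    """
    a, b, c = distortion
    true_mz = np.array([sodiated_mz(r.composition) for r in gly3_standards()])
    distorted = a * true_mz**2 + b * true_mz + c
    if not (np.diff(distorted) > 0).all():
        raise ValueError("distortion is not monotone over the calibrant masses")
    n = true_mz.size
    return PeakList(distorted, np.full(n, intensity), np.full(n, snr))


def default_kidney_spec(seed: int = 0) -> PhantomSpec:
    """The default two-region kidney phantom.

    Planted species and their localisation follow the murine-kidney
    N-glycome: the high-mannose series plus two fucosylated complex
    glycans shared across the tissue, four fucosylated complex glycans
    confined to the cortex, and two species enriched in the medulla.
    Present-in-region prevalence is 0.94 (15/16, the occurrence level
    reported for the in situ profiling spots) and the buffer-control
    tissue carries no glycans at all.
    """

    def pg(name, comp, p_cor, p_med, p_ctl, inten=400.0):
        return PlantedGlycan(
            name, GlycanComposition.from_string(comp), p_cor, p_med, p_ctl, inten
        )

    present, trace = 0.94, 0.06
    planted = [
        # shared across cortex and medulla
        pg("Man5GlcNAc2", "Hex5HexNAc2", present, present, 0.0, 800.0),
        pg("Man6GlcNAc2", "Hex6HexNAc2", present, present, 0.0, 600.0),
        pg("Man7GlcNAc2", "Hex7HexNAc2", present, present, 0.0, 500.0),
        pg("Man8GlcNAc2", "Hex8HexNAc2", present, present, 0.0, 450.0),
        pg("Hex4HexNAc5dHex1", "Hex4HexNAc5dHex1", present, present, 0.0, 300.0),
        pg("Hex3HexNAc4dHex1", "Hex3HexNAc4dHex1", present, present, 0.0, 350.0),
        # cortex-specific
        pg("Hex5HexNAc5dHex3", "Hex5HexNAc5dHex3", present, trace, 0.0, 500.0),
        pg("Hex5HexNAc5dHex2", "Hex5HexNAc5dHex2", present, trace, 0.0, 400.0),
        pg("Hex5HexNAc4dHex1", "Hex5HexNAc4dHex1", present, trace, 0.0, 450.0),
        pg("Hex6HexNAc6dHex4", "Hex6HexNAc6dHex4", present, trace, 0.0, 250.0),
        # medulla-enriched
        pg("Man9GlcNAc2", "Hex9HexNAc2", trace, present, 0.0, 400.0),
        pg("Hex5HexNAc4", "Hex5HexNAc4", trace, present, 0.0, 350.0),
    ]
    return PhantomSpec(planted=planted, seed=seed)


def make_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[ImagingDataset, PhantomTruth]:
    """Generate an imaging dataset and its ground truth from a phantom spec.

    ``seed`` overrides ``spec.seed``; the same seed yields a
    byte-identical dataset.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    masks = spec.masks()
    lo, hi = spec.mz_range

    region_grid = np.full((spec.ny, spec.nx), "none", dtype=object)
    region_grid[masks["treated"]] = "treated"
    region_grid[masks["control"]] = "control"
    region_grid[masks["calibrant"]] = "calibrant"

    gly3_mz = np.array([sodiated_mz(r.composition) for r in gly3_standards()])

    spots: list[SpotMeta] = []
    peaklists: dict[str, PeakList] = {}
    for y in range(spec.ny):
        for x in range(spec.nx):
            region = str(region_grid[y, x])
            sid = f"x{x:03d}y{y:03d}"
            mz_list: list[float] = []
            int_list: list[float] = []
            snr_list: list[float] = []

            if region == "calibrant":
                for m in gly3_mz:
                    mz_list.append(m + rng.normal(0.0, spec.jitter_sigma))
                    int_list.append(
                        float(5000.0 * rng.lognormal(0.0, spec.intensity_log_sigma))
                    )
                    snr_list.append(float(spec.snr_floor + rng.exponential(50.0)))
            else:
                for g in spec.planted:
                    if masks["cortex"][y, x]:
                        p = g.prevalence_cortex
                    elif masks["medulla"][y, x]:
                        p = g.prevalence_medulla
                    elif masks["control"][y, x]:
                        p = g.prevalence_control
                    else:
                        p = 0.0
                    if p > 0 and rng.random() < p:
                        mz_list.append(
                            g.sodiated_mz + rng.normal(0.0, spec.jitter_sigma)
                        )
                        int_list.append(
                            float(
                                g.intensity_median
                                * rng.lognormal(0.0, spec.intensity_log_sigma)
                            )
                        )
                        snr_list.append(
                            float(spec.snr_floor + rng.exponential(spec.snr_scale))
                        )
                        if (
                            spec.glycosylamine_fraction > 0
                            and g.composition.hexnac >= 1
                            and rng.random() < spec.glycosylamine_fraction
                        ):
                            mz_list.append(
                                g.sodiated_mz
                                + GLYCOSYLAMINE_SHIFT
                                + rng.normal(0.0, spec.jitter_sigma)
                            )
                            int_list.append(0.5 * int_list[-1])
                            snr_list.append(
                                float(
                                    spec.snr_floor
                                    + rng.exponential(spec.snr_scale / 2)
                                )
                            )

            n_noise = rng.poisson(spec.noise_rate)
            for _ in range(n_noise):
                mz_list.append(float(rng.uniform(lo, hi)))
                int_list.append(
                    float(
                        spec.noise_intensity_median
                        * rng.lognormal(0.0, spec.intensity_log_sigma)
                    )
                )
                snr_list.append(
                    float(spec.snr_floor + rng.exponential(spec.noise_snr_scale))
                )

            spots.append(SpotMeta(sid, x, y, region))
            peaklists[sid] = PeakList(
                np.array(mz_list), np.array(int_list), np.array(snr_list)
            )

    dataset = ImagingDataset(spots, peaklists, mz_range=spec.mz_range)

    n_cortex = int(masks["cortex"].sum())
    n_medulla = int(masks["medulla"].sum())
    n_treated = n_cortex + n_medulla
    rows = []
    for g in spec.planted:
        p_t = (
            (n_cortex * g.prevalence_cortex + n_medulla * g.prevalence_medulla)
            / n_treated
        )
        rows.append(
            {
                "name": g.name,
                "sodiated_mz": g.sodiated_mz,
                "prevalence_cortex": g.prevalence_cortex,
                "prevalence_medulla": g.prevalence_medulla,
                "prevalence_control": g.prevalence_control,
                "p_treated": p_t,
                "expected_dipps": p_t - g.prevalence_control,
            }
        )
    truth = PhantomTruth(pd.DataFrame(rows), masks)
    return dataset, truth
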