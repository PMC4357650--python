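"""Glycan composition mass arithmetic and ppm-tolerance annotation.

An N-glycan composition is a multiset of monosaccharide residue classes
(Hex, HexNAc, deoxyhexose/fucose, NeuAc, NeuGc).  The neutral monoisotopic
mass of a glycan is the sum of its residue masses plus one water (the
residue masses are dehydrated).  From the neutral mass the module derives
the ion species relevant to MALDI-TOF and negative-mode LC-MS glycomics:

* ``[M+Na]+`` — the dominant MALDI adduct of underivatised glycans; the
  adduct increment is the sodium atom mass minus one electron.
* the glycosylamine form — PNGase F initially releases N-glycans as
  glycosylamines (NH at the reducing-end HexNAc C1 instead of OH),
  0.984016 Da *below* the free-reducing-end form; the two species explain
  an apparent ~1 Da discrepancy between measurement modes.
* alditol ions — after borohydride reduction the open-ring alditol is
  2.015650 Da heavier than M; ``[M-H]-`` and ``[M-2H]2-`` are computed
  from the reduced mass for comparison with negative-mode LC-MS.

All constants are CODATA/IUPAC monoisotopic values to six decimals.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GlycanComposition",
    "GlycanRecord",
    "AnnotationMatch",
    "RESIDUE_MASSES",
    "WATER",
    "PROTON",
    "NA_ADDUCT",
    "GLYCOSYLAMINE_SHIFT",
    "ALDITOL_SHIFT",
    "ION_FORMS",
    "composition_mass",
    "sodiated_mz",
    "glycosylamine_sodiated_mz",
    "alditol_ion_mz",
    "ion_mz",
    "ppm_error",
    "annotate_mass",
    "load_glycan_library",
    "save_glycan_library",
    "gly3_standards",
    "kidney_nglycans",
]

# Monoisotopic residue (dehydrated) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "hex": 162.052824,
    "hexnac": 203.079373,
    "dhex": 146.057909,
    "neuac": 291.095417,
    "neugc": 307.090331,
}

WATER = 18.010565
PROTON = 1.0072765
SODIUM = 22.989770
ELECTRON = 0.0005486
#: [M+Na]+ increment: one sodium atom minus the electron carried away.
NA_ADDUCT = SODIUM - ELECTRON
#: glycosylamine (reducing-end NH2) relative to the free reducing end.
GLYCOSYLAMINE_SHIFT = -0.984016
#: open-ring alditol (reduced) relative to the free reducing end (+H2).
ALDITOL_SHIFT = 2.015650

# Synonyms accepted by the composition parser, lower-cased.
_RESIDUE_SYNONYMS = {
    "hex": "hex",
    "man": "hex",
    "gal": "hex",
    "glc": "hex",
    "hexnac": "hexnac",
    "glcnac": "hexnac",
    "galnac": "hexnac",
    "dhex": "dhex",
    "fuc": "dhex",
    "deoxyhexose": "dhex",
    "neuac": "neuac",
    "neugc": "neugc",
}

_TOKEN_RE = re.compile(r"\(?\s*([A-Za-z]+)\s*\)?\s*_?(\d*)_?")


class InvalidCompositionError(ValueError):
    """Raised for negative counts or unparseable composition strings."""


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide residue classes defining a neutral glycan.

    The all-zero composition is legal and has the mass of one water.
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0
    neugc: int = 0

    def __post_init__(self) -> None:
        for field in ("hex", "hexnac", "dhex", "neuac", "neugc"):
            value = getattr(self, field)
            if not isinstance(value, int) or value < 0:
                raise InvalidCompositionError(
                    f"{field} count must be a non-negative integer, got {value!r}"
                )

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hex + other.hex,
            self.hexnac + other.hexnac,
            self.dhex + other.dhex,
            self.neuac + other.neuac,
            self.neugc + other.neugc,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "hex": self.hex,
            "hexnac": self.hexnac,
            "dhex": self.dhex,
            "neuac": self.neuac,
            "neugc": self.neugc,
        }

    def __str__(self) -> str:
        labels = {
            "hex": "Hex",
            "hexnac": "HexNAc",
            "dhex": "dHex",
            "neuac": "NeuAc",
            "neugc": "NeuGc",
        }
        parts = [
            f"{labels[k]}{v}" for k, v in self.as_dict().items() if v > 0
        ]
        return "".join(parts) if parts else "Free"

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        """Parse a composition written in either total or delta-plus-core form.

        Accepts ``Hex5HexNAc2``, ``Man5GlcNAc2``, ``(Hex)2 (HexNAc)2 +
        (Man)3(GlcNAc)2`` and similar.  ``+``-separated parts are summed, so
        the common "antenna + (Man)3(GlcNAc)2 core" notation folds into
        total Hex/HexNAc counts.  A bare residue name counts once.
        """
        counts = {k: 0 for k in RESIDUE_MASSES}
        for part in text.split("+"):
            part = part.strip()
            if not part:
                continue
            matched_any = False
            consumed = 0
            for m in _TOKEN_RE.finditer(part):
                name = m.group(1).lower()
                if name not in _RESIDUE_SYNONYMS:
                    raise InvalidCompositionError(
                        f"unknown residue {m.group(1)!r} in {text!r}"
                    )
                n = int(m.group(2)) if m.group(2) else 1
                counts[_RESIDUE_SYNONYMS[name]] += n
                matched_any = True
                consumed = m.end()
            if not matched_any or re.search(r"[A-Za-z0-9]", part[consumed:]):
                raise InvalidCompositionError(f"cannot parse composition {text!r}")
        return cls(**counts)


def composition_mass(c: GlycanComposition) -> float:
    """Neutral monoisotopic mass [M] in Da: sum of residues plus one water."""
    return (
        c.hex * RESIDUE_MASSES["hex"]
        + c.hexnac * RESIDUE_MASSES["hexnac"]
        + c.dhex * RESIDUE_MASSES["dhex"]
        + c.neuac * RESIDUE_MASSES["neuac"]
        + c.neugc * RESIDUE_MASSES["neugc"]
        + WATER
    )


def sodiated_mz(c: GlycanComposition) -> float:
    """m/z of the singly sodiated positive ion [M+Na]+."""
    return composition_mass(c) + NA_ADDUCT


def glycosylamine_sodiated_mz(c: GlycanComposition) -> float:
    """[M+Na]+ of the glycosylamine form (requires a reducing-end HexNAc)."""
    if c.hexnac < 1:
        raise InvalidCompositionError(
            "glycosylamine form requires at least one HexNAc (reducing end)"
        )
    return sodiated_mz(c) + GLYCOSYLAMINE_SHIFT


def alditol_ion_mz(c: GlycanComposition, charge: int = 2) -> float:
    """Negative-mode ion of the reduced (alditol) glycan.

    ``charge=1`` gives [M_red - H]-, ``charge=2`` gives [M_red - 2H]2-.
    """
    m_red = composition_mass(c) + ALDITOL_SHIFT
    if charge == 1:
        return m_red - PROTON
    if charge == 2:
        return (m_red - 2.0 * PROTON) / 2.0
    raise ValueError(f"unsupported charge {charge}; expected 1 or 2")


#: ion-form label -> function(composition) -> m/z
ION_FORMS = {
    "M": composition_mass,
    "M+Na": sodiated_mz,
    "M-H": lambda c: composition_mass(c) - PROTON,
    "M-2H": lambda c: (composition_mass(c) - 2.0 * PROTON) / 2.0,
    "glycosylamine+Na": glycosylamine_sodiated_mz,
    "alditol-H": lambda c: alditol_ion_mz(c, charge=1),
    "alditol-2H": lambda c: alditol_ion_mz(c, charge=2),
}


def ion_mz(c: GlycanComposition, form: str) -> float:
    """m/z of composition ``c`` in the named ion form (see ``ION_FORMS``)."""
    try:
        fn = ION_FORMS[form]
    except KeyError:
        raise ValueError(
            f"unknown ion form {form!r}; known: {sorted(ION_FORMS)}"
        ) from None
    return fn(c)


def ppm_error(observed: float, calculated: float) -> float:
    """Signed relative mass error in parts per million.

    Positive when the observed m/z exceeds the calculated one.
    """
    if calculated <= 0:
        raise ValueError("calculated mass must be positive")
    return 1e6 * (observed - calculated) / calculated


@dataclass(frozen=True)
class GlycanRecord:
    """A named library entry: composition plus optional reference [M+Na]+."""

    name: str
    composition: GlycanComposition
    reference_sodiated_mz: float | None = None

    def __post_init__(self) -> None:
        if self.reference_sodiated_mz is not None:
            delta = abs(self.reference_sodiated_mz - sodiated_mz(self.composition))
            if delta > 0.002:
                raise ValueError(
                    f"{self.name}: reference sodiated m/z "
                    f"{self.reference_sodiated_mz} is {delta:.4f} Da from the "
                    f"computed value {sodiated_mz(self.composition):.4f}"
                )


@dataclass(frozen=True)
class AnnotationMatch:
    """One (record, ion form) pair matching an observed m/z within tolerance."""

    observed_mz: float
    record: GlycanRecord
    ion_form: str
    calculated_mz: float
    ppm: float


def annotate_mass(
    observed: float,
    library: Sequence[GlycanRecord],
    forms: Iterable[str] = ("M+Na",),
    tolerance_ppm: float = 100.0,
) -> list[AnnotationMatch]:
    """All library (record, ion form) pairs within ``tolerance_ppm`` of ``observed``.

    Matches are sorted by absolute ppm error; an empty library or no match
    yields an empty list.  Forms inapplicable to a record (glycosylamine
    without HexNAc) are silently skipped.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    matches: list[AnnotationMatch] = []
    for record in library:
        for form in forms:
            try:
                calc = ion_mz(record.composition, form)
            except InvalidCompositionError:
                continue
            err = ppm_error(observed, calc)
            if abs(err) <= tolerance_ppm:
                matches.append(
                    AnnotationMatch(observed, record, form, calc, err)
                )
    matches.sort(key=lambda m: abs(m.ppm))
    return matches


# ---------------------------------------------------------------------------
# Library IO

_LIBRARY_COLUMNS = ["name", "hex", "hexnac", "dhex", "neuac", "neugc"]


def load_glycan_library(path) -> list[GlycanRecord]:
    """Read a glycan library CSV (name, residue counts, optional reference m/z)."""
    df = pd.read_csv(path)
    missing = [c for c in _LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library {path} missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        comp = GlycanComposition(
            *(int(row[c]) for c in ("hex", "hexnac", "dhex", "neuac", "neugc"))
        )
        ref = row.get("reference_sodiated_mz")
        ref = None if ref is None or pd.isna(ref) else float(ref)
        records.append(GlycanRecord(str(row["name"]), comp, ref))
    return records


def save_glycan_library(records: Sequence[GlycanRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LIBRARY_COLUMNS + ["reference_sodiated_mz"])
        for r in records:
            d = r.composition.as_dict()
            writer.writerow(
                [r.name, d["hex"], d["hexnac"], d["dhex"], d["neuac"], d["neugc"],
                 "" if r.reference_sodiated_mz is None else r.reference_sodiated_mz]
            )


def _data_path(name: str):
    return resources.files("glycomsi.data").joinpath(name)


def gly3_standards() -> list[GlycanRecord]:
    """The three-component N-glycan calibration standard mixture (GLY3)."""
    with resources.as_file(_data_path("gly3.csv")) as p:
        return load_glycan_library(p)


def kidney_nglycans() -> pd.DataFrame:
    """Murine-kidney N-glycan reference table.

    Columns: ``name``, residue counts, ``observed_awm_mz`` (the abundance
    weighted mean [M+Na]+ measured by MALDI imaging) and ``awm_set``
    ("top13" for the nine glycans among the 13 highest-DIPPS m/z values,
    "top26" for the further seven among the top 26).
    """
    with resources.as_file(_data_path("kidney_nglycans.csv")) as p:
        return pd.read_csv(p)


def kidney_nglycan_records() -> list[GlycanRecord]:
    """``kidney_nglycans`` as GlycanRecord objects (without observed m/z)."""
    df = kidney_nglycans()
    return [
        GlycanRecord(
            str(row["name"]),
            GlycanComposition(
                *(int(row[c]) for c in ("hex", "hexnac", "dhex", "neuac", "neugc"))
            ),
        )
        for _, row in df.iterrows()
    ]
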