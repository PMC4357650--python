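"""Glycan composition mass arithmetic and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycomsi import mass
from glycomsi.mass import (
    GlycanComposition,
    GlycanRecord,
    InvalidCompositionError,
    annotate_mass,
    alditol_ion_mz,
    composition_mass,
    glycosylamine_sodiated_mz,
    ion_mz,
    ppm_error,
    sodiated_mz,
)

compositions = st.builds(
    GlycanComposition,
    hex=st.integers(0, 12),
    hexnac=st.integers(0, 8),
    dhex=st.integers(0, 5),
    neuac=st.integers(0, 4),
    neugc=st.integers(0, 4),
)


class TestCompositionMass:
    @pytest.mark.parametrize(
        "comp, expected_m, expected_mna",
        [
            (GlycanComposition(hex=5, hexnac=2), 1234.4333, 1257.4225),
            (GlycanComposition(hex=3, hexnac=5), 1519.5659, 1542.5551),
            (GlycanComposition(hex=7, hexnac=6), 2370.8565, 2393.8457),
        ],
    )
    def test_gly3_standard_masses(self, comp, expected_m, expected_mna):
        """The three calibration-standard [M] and [M+Na]+ values."""
        assert composition_mass(comp) == pytest.approx(expected_m, abs=0.001)
        assert sodiated_mz(comp) == pytest.approx(expected_mna, abs=0.001)

    def test_empty_composition_is_water(self):
        assert composition_mass(GlycanComposition()) == pytest.approx(18.0106, abs=1e-4)
        assert sodiated_mz(GlycanComposition()) == pytest.approx(40.9998, abs=1e-4)

    def test_hand_summed_high_mannose(self):
        # 9*162.052824 + 2*203.079373 + 18.010565
        assert composition_mass(
            GlycanComposition(hex=9, hexnac=2)
        ) == pytest.approx(1882.644727, abs=1e-6)

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidCompositionError):
            GlycanComposition(hex=-1)

    @given(a=compositions, b=compositions)
    @settings(max_examples=100, deadline=None)
    def test_mass_additivity(self, a, b):
        """mass(a+b) = mass(a) + mass(b) - water (one fewer free water)."""
        assert composition_mass(a + b) == pytest.approx(
            composition_mass(a) + composition_mass(b) - mass.WATER, abs=1e-9
        )

    @given(c=compositions)
    @settings(max_examples=100, deadline=None)
    def test_sodiated_offset_constant(self, c):
        assert sodiated_mz(c) - composition_mass(c) == pytest.approx(
            22.989221, abs=1e-6
        )


class TestDerivativeForms:
    def test_glycosylamine_one_dalton_below(self):
        c = GlycanComposition(hex=5, hexnac=5, dhex=3)
        assert sodiated_mz(c) == pytest.approx(2304.83, abs=0.01)
        assert sodiated_mz(c) - glycosylamine_sodiated_mz(c) == pytest.approx(
            0.984016, abs=1e-9
        )

    def test_glycosylamine_man5(self):
        c = GlycanComposition(hex=5, hexnac=2)
        assert glycosylamine_sodiated_mz(c) == pytest.approx(1256.4386, abs=0.001)

    def test_glycosylamine_needs_reducing_hexnac(self):
        with pytest.raises(InvalidCompositionError):
            glycosylamine_sodiated_mz(GlycanComposition(hex=5))

    def test_alditol_singly_charged(self):
        # reduced high-mannose Man5 in negative mode
        c = GlycanComposition(hex=5, hexnac=2)
        assert alditol_ion_mz(c, charge=1) == pytest.approx(1235.44, abs=0.01)

    def test_alditol_doubly_charged(self):
        c = GlycanComposition(hex=5, hexnac=4)
        assert alditol_ion_mz(c, charge=2) == pytest.approx(820.2968, abs=0.001)

    @given(c=compositions)
    @settings(max_examples=50, deadline=None)
    def test_alditol_charge_state_identity(self, c):
        """2*mz2 + 2*proton = mz1 + proton (same reduced neutral mass)."""
        mz1 = alditol_ion_mz(c, charge=1)
        mz2 = alditol_ion_mz(c, charge=2)
        assert 2 * mz2 + 2 * mass.PROTON == pytest.approx(
            mz1 + mass.PROTON, abs=1e-9
        )

    def test_unsupported_charge(self):
        with pytest.raises(ValueError):
            alditol_ion_mz(GlycanComposition(hex=5, hexnac=2), charge=3)


class TestPpmError:
    def test_zero_for_exact_match(self):
        assert ppm_error(1500.0, 1500.0) == 0.0

    def test_man5_observed_vs_calculated(self):
        assert ppm_error(1257.473, 1257.4226) == pytest.approx(40.1, abs=0.1)

    def test_sign_convention(self):
        assert ppm_error(1000.0, 1000.1) == pytest.approx(-100.0, abs=0.01)

    def test_nonpositive_calculated_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(1000.0, 0.0)


class TestParser:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Hex5HexNAc2", GlycanComposition(hex=5, hexnac=2)),
            ("Man5GlcNAc2", GlycanComposition(hex=5, hexnac=2)),
            (
                "(Hex)2 (HexNAc)2 + (Man)3(GlcNAc)2",
                GlycanComposition(hex=5, hexnac=4),
            ),
            (
                "(Hex)2(HexNAc)3(Deoxyhexose)3 + (Man)3(GlcNAc)2",
                GlycanComposition(hex=5, hexnac=5, dhex=3),
            ),
            ("Man3Gal4GlcNAc6", GlycanComposition(hex=7, hexnac=6)),
            ("Fuc", GlycanComposition(dhex=1)),
        ],
    )
    def test_total_and_delta_plus_core_notations(self, text, expected):
        assert GlycanComposition.from_string(text) == expected

    def test_unknown_residue_rejected(self):
        with pytest.raises(InvalidCompositionError):
            GlycanComposition.from_string("Xyl2Hex3")


class TestAnnotation:
    def test_man5_match_in_kidney_library(self):
        records = mass.kidney_nglycan_records()
        matches = annotate_mass(1257.473, records, forms=["M+Na"], tolerance_ppm=100)
        assert matches and matches[0].record.name == "Man5GlcNAc2"
        assert matches[0].ppm == pytest.approx(40.0, abs=0.1)

    def test_tight_tolerance_gives_empty(self):
        records = mass.gly3_standards()
        assert annotate_mass(1257.473, records, tolerance_ppm=0.001) == []

    def test_exact_mass_zero_ppm(self):
        records = mass.gly3_standards()
        target = sodiated_mz(records[0].composition)
        matches = annotate_mass(target, records, tolerance_ppm=10)
        assert matches[0].ppm == 0.0

    def test_empty_library(self):
        assert annotate_mass(1257.4, [], tolerance_ppm=100) == []

    @given(
        observed=st.floats(900.0, 3000.0),
        tol=st.floats(1.0, 500.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_brute_force_scan(self, observed, tol, seed):
        """annotate_mass equals an exhaustive (record x form) scan."""
        rng = np.random.default_rng(seed)
        records = [
            GlycanRecord(
                f"g{i}",
                GlycanComposition(
                    hex=int(rng.integers(0, 10)),
                    hexnac=int(rng.integers(0, 7)),
                    dhex=int(rng.integers(0, 4)),
                ),
            )
            for i in range(40)
        ]
        forms = ["M+Na", "M", "glycosylamine+Na", "alditol-2H"]
        got = annotate_mass(observed, records, forms=forms, tolerance_ppm=tol)
        expected = []
        for r in records:
            for f in forms:
                if f == "glycosylamine+Na" and r.composition.hexnac == 0:
                    continue
                calc = ion_mz(r.composition, f)
                err = 1e6 * (observed - calc) / calc
                if abs(err) <= tol:
                    expected.append((r.name, f))
        assert sorted((m.record.name, m.ion_form) for m in got) == sorted(expected)
        ppms = [abs(m.ppm) for m in got]
        assert ppms == sorted(ppms)


class TestLibraries:
    def test_gly3_references_consistent(self):
        # GlycanRecord validates reference vs computed mass on construction
        records = mass.gly3_standards()
        assert [r.name for r in records] == [
            "Man5GlcNAc2", "Man3GlcNAc5", "Man3Gal4GlcNAc6",
        ]

    def test_inconsistent_reference_rejected(self):
        with pytest.raises(ValueError):
            GlycanRecord(
                "bad", GlycanComposition(hex=5, hexnac=2), reference_sodiated_mz=1258.0
            )

    def test_round_trip_csv(self, tmp_path):
        records = mass.gly3_standards()
        path = tmp_path / "lib.csv"
        mass.save_glycan_library(records, path)
        assert mass.load_glycan_library(path) == records
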