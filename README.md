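# glycomsi

Analysis toolkit for **N-glycan MALDI imaging mass spectrometry** of
FFPE tissue.  When PNGase F is printed onto a formalin-fixed tissue
section, it releases N-linked glycans in place; MALDI-TOF spectra
acquired over the section then contain glycan ions on top of matrix and
chemical noise.  `glycomsi` implements the data-analysis layer of such an
experiment for mass spectrometrists and computational glycomics
researchers:

- **Glycan mass arithmetic** — a composition `(Hex)_h (HexNAc)_n (dHex)_f
  (NeuAc)_s (NeuGc)_g` has neutral monoisotopic mass
  `M = Σ count·residue + H₂O`; derived ions include the MALDI adduct
  `[M+Na]⁺ = M + (Na − e⁻)`, the PNGase F glycosylamine form
  (`−0.984016 Da`), and reduced alditol ions `[M−H]⁻`, `[M−2H]²⁻` for
  negative-mode LC-MS cross-checks.  Annotation is by signed ppm error
  within a tolerance.
- **Preprocessing** — TopHat (morphological opening) baseline
  subtraction, TIC/RMS normalisation, peak-preserving data reduction,
  quadratic internal recalibration against a three-component glycan
  standard (GLY3), and 0.5 Da binning into a spot × m/z matrix.
- **Peak grouping** — single-linkage clustering of all peaks along m/z
  with a 0.1 m/z linkage distance; each group gets an
  **abundance-weighted mean** m/z, `AWM = Σ mᵢ·(S/N)ᵢ / Σ (S/N)ᵢ`, and
  per-region spot-occurrence counts.  Candidate filters: present in ≥2
  enzyme-treated and ≤1 buffer-control spots above m/z 1000 (profiling),
  or in ≥100 spectra (imaging).
- **DIPPS** — the difference in proportions of occurrence,
  `DIPPS = p_treated − p_control ∈ [−1, 1]`, ranked per peak group, with
  a data-dependent cutoff heuristic or user top-N selection, spatial
  DIPPS maps (per-spot counts of selected groups) and log
  ion-intensity maps.
- **Multivariate spatial summaries** — bisecting k-means segmentation
  under correlation distance and EM-fit pLSA
  (`P(s,b) = Σ_z P(z)P(s|z)P(b|z)`), both as scikit-learn estimators.
- **Phantom generator** — fully ground-truthed synthetic kidney sections
  (cortex/medulla anatomy, treated/control/calibrant regions, planted
  glycans with per-region prevalence, m/z jitter, noise peaks) so every
  pipeline stage is testable without instrument data.

## Worked example

```python
from glycomsi.mass import (GlycanComposition, composition_mass, sodiated_mz,
                           ppm_error, annotate_mass, kidney_nglycan_records)

comp = GlycanComposition.from_string("(Hex)2(HexNAc)3(Deoxyhexose)3 + (Man)3(GlcNAc)2")
print(comp)
print(f"[M]      = {composition_mass(comp):.4f}")
print(f"[M+Na]+  = {sodiated_mz(comp):.4f}")
print(f"ppm error of observed 2304.909: {ppm_error(2304.909, sodiated_mz(comp)):+.1f}")

match = annotate_mass(2304.909, kidney_nglycan_records(), forms=["M+Na"], tolerance_ppm=100)[0]
print(f"best annotation: {match.record.name} ({match.ion_form}, {match.ppm:+.1f} ppm)")
```

prints

```
Hex5HexNAc5dHex3
[M]      = 2281.8453
[M+Na]+  = 2304.8345
ppm error of observed 2304.909: +32.3
best annotation: Hex5HexNAc5dHex3 (M+Na, +32.3 ppm)
```

The composition parser folds the "antenna + (Man)₃(GlcNAc)₂ core"
notation into total residue counts (here Hex₅HexNAc₅dHex₃, a
tri-fucosylated complex glycan).  The neutral and sodiated masses are
monoisotopic; the +32 ppm error is typical of an externally calibrated
TOF measurement, and annotation ranks all library matches by |ppm|.

End-to-end on synthetic data:

```bash
glycomsi simulate --out phantom/ --seed 1
glycomsi dipps --manifest phantom/manifest.csv --select topn --n 12 --out phantom/dipps
glycomsi segment --manifest phantom/manifest.csv --leaves 2 --seed 1 --out phantom/segments.csv
```

`phantom/dipps_table.csv` ranks every peak group occurring in ≥100
spectra by DIPPS (the planted glycans occupy the top ranks with DIPPS
between ~0.9 for tissue-wide species and ~0.28 for medulla-restricted
ones), and `phantom/dipps_map.csv` holds the per-spot counts of the
selected groups.

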