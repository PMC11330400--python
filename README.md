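# pfas-screen

Suspect screening of per- and polyfluoroalkyl substances (PFAS) in
**direct-infusion ultra-high-resolution mass spectrometry** peak lists.
The package is aimed at environmental analytical chemists who acquire
windowed (CASI / spectral-stitching) FT-ICR MS data of complex extracts
— biota, water, AFFF-impacted samples — and want an automated,
scriptable path from calibrated centroid peak lists to a short, ranked
list of plausible PFAS candidates, without chromatographic separation.

## What it does

1. **Suspect-list curation** — a raw CSV whose first column is
   `Molecular formula` (CompTox-PFASMASTER-like) is turned into a
   machine-readable list: monoisotopic masses are *recomputed* from the
   formula, counter-cations (Na⁺, K⁺, Li⁺, NH₄⁺, Cs⁺, Ag⁺) are stripped
   from salts so a salt and its free acid share one deprotonated mass,
   and every entry gets its single-substitution isotopologues
   (¹³C, ³⁴S, ¹⁸O, ³⁷Cl, ⁸¹Br, ²⁹Si), elemental descriptors
   (F/C, H/C, (H+F)/C, O/C, (H+Hal)/C, (O+S+P+N)/C, DBE, DBE−O, mass
   defect) and an ionizability class derived from predicted pKa values.
2. **Peak-list handling** — per-window CSV peak lists (m/z, intensity,
   S/N) are filtered at S/N ≥ 4, trimmed to their CASI window ± 5 Da
   (so isotopologues of edge compounds are kept), stitched with
   duplicate retention, and optionally blank-filtered.
3. **Matching** — each suspect's [M−H]⁻ mass
   (m = M − 1.007277 Da) is paired with its k = 10 nearest measured
   m/z values; pairs within 1.5 ppm become candidate annotations.
   Near-isobars (e.g. C₁₁H₆Cl₂F₆N₂ at 349.98122 Da and C₆H₂F₁₂O₃ at
   349.98123 Da, 0.03 ppm apart) are both retained.
4. **Isotopologue validation** — for each candidate, every isotopologue
   predicted above the detection floor is compared with the nearest
   measured peak in two scale-free coordinates, the mass deviation
   Δppm and the relative intensity deviation Δ% :

       d  = √(Δppm² + Δ%²)
       sᵢ = 1 / (1 + dᵢ)
       score = 100 · Σᵢ sᵢ wᵢ ,   wᵢ = predicted intensityᵢ / Σ predicted

   A perfect pattern scores 100; an expected-but-missing isotopologue
   contributes sᵢ = 0 at full weight. Candidates with at least one
   expected isotopologue are level **L-4** (scored); candidates whose
   isotopologues all fall below the floor are **L-5** (accurate mass
   only).
5. **Funnel and ranking** — duplicates (window overlap, salt/acid
   twins) are removed keeping the higher S/N; L-4 candidates below
   score 75 are dropped; non-ionizable and electropositive (basic-only)
   suspects are excluded; heteroatom-free compositions
   ((O+S+P+N)/C = 0, likely in-source fragments) are removed; the
   survivors are ranked by the mean of min–max-normalized |ppm error|,
   QC level and acidic pKa (0 = best). Every stage's in/out counts are
   recorded in a conservation-checked funnel report.

A seeded synthetic-data generator produces ground-truthed windowed peak
lists (spiked PFAS with theoretical isotopologue patterns, ppm jitter,
intensity noise, decoy matrix peaks, blank-overlap peaks) so the whole
pipeline is testable offline.

## Worked example

```bash
pfas-screen simulate --out demo --seed 1
pfas-screen screen --suspects demo/suspects.csv --peaks demo \
    --blank demo/blank.csv --out demo_out
```

The screen step logs the candidate funnel:

```
dedup: 33 -> 26 (-7: duplicate charged mass)
similarity_threshold: 26 -> 26 (-0: isotope score < 75)
pka_non_ionizable: 26 -> 24 (-2: no ionizable site)
pka_electropositive: 24 -> 22 (-2: positive-mode only)
fragment_exclusion: 22 -> 20 (-2: (O+S+P+N)/C = 0)
```

33 raw annotations (20 spiked acids plus a PFOS potassium-salt twin,
window-overlap duplicates, and the decoy suspects that were spiked to
exercise each filter) collapse to exactly the 20 spiked acidic PFAS.
`demo_out/final_candidates.csv` lists them with rank, composite score,
ppm error (0 in the noiseless default), isotope score (100) and level:

```
rank suspect_id  ppm_error  score level
   1    PFSA_C4        0.0  100.0    L4
   2    PFSA_C9        0.0  100.0    L4
   3    PFSA_C5        0.0  100.0    L4
   ...
```

The same can be done from Python:

```python
from pfas_screen.synthetic import default_dataset
from pfas_screen.pipeline import screen

ds = default_dataset(seed=1)
res = screen(ds.spectra, ds.suspects, blank=ds.blank)
print(res.funnel)          # stage-by-stage counts, conservation-checked
print(res.final.head())    # ranked candidate table
```

Chemistry core, briefly:

```python
>>> from pfas_screen import parse_formula, monoisotopic_mass, charged_mass
>>> charged_mass(monoisotopic_mass(parse_formula("C8HF17O3S")))  # PFOS [M-H]-
498.9302176307501
```

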