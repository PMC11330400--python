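# Methods

## Scope and model

`pfas-screen` implements suspect screening for anionic PFAS in
negative-ESI direct-infusion ultra-high-resolution MS. The underlying
assumptions are those of the measurement mode it targets:

* **Ionization.** Deprotonation [M−H]⁻ is taken as the dominant ion
  formation process. The deprotonated mass is computed as
  `neutral − 1.007277 Da`, i.e. the proton mass with no separate
  electron-mass bookkeeping. This convention is used consistently on
  both the suspect side and the deconvolution side, so the two cancel;
  it reproduces the conventional reference value for the PFOS anion
  (498.93022 Da) exactly. Multiply charged species and positive-mode
  adducts are out of scope; the `IonForm` type reserves the interface
  for future modes.
* **Salts.** A recognized monovalent counter-cation (Na⁺, K⁺, Li⁺,
  NH₄⁺, Cs⁺, Ag⁺) is stripped and the anion is *re-protonated* to the
  parent acid before the standard deprotonation arithmetic is applied.
  This guarantees — bit-identically, not approximately — that a salt
  and its free acid share one charged mass, which is what the
  downstream deduplication keys on. (Summing atomic masses of the bare
  anion composition instead would differ by the electron mass,
  0.00055 Da ≈ 1.1 ppm at m/z 500, enough to break matching at a
  1.5 ppm tolerance.) Multivalent salts (Ca²⁺, Mg²⁺, …) are not
  stripped: assigning half a cation would fabricate a charge state, so
  such entries fall back to neutral-parent treatment with a warning and
  stay in the screening rather than being silently excluded.
* **Isotopologues.** Patterns are single substitutions of the most
  abundant heavy isotope of C, S, O, Cl, Br and Si only (¹³C, ³⁴S,
  ¹⁸O, ³⁷Cl, ⁸¹Br, ²⁹Si). The relative abundance of a single
  substitution is `n_E · a_heavy / a_light` — the first-order term of
  the binomial pattern. Double substitutions (³⁷Cl₂, ¹³C¹⁸O, …) are
  deliberately ignored: at natural abundance they are an order of
  magnitude weaker and rarely clear the detection floor, and omitting
  them keeps every suspect's pattern the same small, predictable set.
  Mass *shifts* (heavy − light) are stored rather than absolute
  isotopologue masses; shifts are mode-independent and are applied to
  the measured monoisotopic m/z at scoring time.
* **Isotope data.** Masses and natural abundances come from the
  NIST/IUPAC table shipped with pyteomics, exposed as a versioned
  `IsotopeTable` that can be exported to CSV and overridden from CSV
  (element, mass number, mass, abundance).

## Scoring

For a candidate with measured monoisotopic peak (m, I), each
isotopologue i is predicted at `m + shift_i` with intensity
`I · ra_i`. An isotopologue is *expected* iff its predicted intensity
is at or above the detection floor; the floor is the minimum retained
intensity **of the source CASI window** (not global), because
detectability differs between windows with different accumulation and
matrix load.

Each expected isotopologue is looked up among the measured peaks within
the global mass tolerance (default 1.5 ppm; ties on |Δppm| go to the
higher-intensity peak) and compared in two dimensionless coordinates:
mass deviation in ppm and intensity deviation in percent of the
predicted intensity. Then

    d_i     = sqrt(Δppm_i² + Δ%_i²)
    s_i     = 1 / (1 + d_i)
    w_i     = predicted_i / Σ_expected predicted
    score   = 100 · Σ_expected s_i · w_i

Choices worth stating explicitly:

* The Δ% denominator is the **predicted** intensity (the theoretical
  pattern is the reference being tested against).
* Expected-but-absent isotopologues keep their full weight at s = 0, so
  a missing signal always lowers the score.
* Sub-floor isotopologues are dropped **before** weight normalization;
  weights always re-sum to 1 over the scored set. (Normalizing before
  dropping would let undetectable isotopologues silently cap the
  maximum attainable score.)
* L-4 = at least one expected isotopologue existed (score defined);
  L-5 = none did (no score; the candidate rests on accurate mass
  alone). L-5 candidates pass the score threshold unfiltered — there is
  nothing to threshold — and rely on the later pKa/fragment filters and
  the composite rank.

The score is in [0, 100], equals 100 iff every expected isotopologue
matches exactly, and decays strictly monotonically in every |Δppm| and
|Δ%| — these invariants are property-tested against an independent
straight-line implementation of the formulas.

## Matching

In one dimension the Euclidean distance between a suspect mass and a
measured m/z is the absolute difference, so the k-nearest-neighbour
search is two binary searches on the sorted stitched m/z array,
widening symmetrically and keeping boundary ties on both sides. The
ppm tolerance (default 1.5) alone decides acceptance; k (default 10)
only caps the number of annotations one suspect can collect. Agreement
with a brute-force all-pairs scan is asserted on dense random
instances up to 1000 × 1000.

## Funnel

Filter order is fixed: dedup → similarity threshold (75) → pKa
exclusion (non-ionizable, then electropositive) → fragment exclusion
((O+S+P+N)/C = 0) → composite rank. Every stage logs (in, removed,
out) into a `FunnelReport`; `check()` enforces `in − removed = out`
per stage and continuity between stages, and runs automatically at the
end of the pipeline.

Ranking normalizes |ppm error| and acidic pKa by min–max over the
surviving candidate set (min → 0 = best) and maps the discrete QC level
1…5 linearly to 0…1; the composite is the unweighted mean. Degenerate
min = max (e.g. a single candidate) maps to 0, not NaN; a kept
candidate missing pKa or QC — which the pKa filter should have made
impossible — gets the worst value 1 with a warning. The absolute value
of the ppm error is used (accuracy, not bias, semantics). Ties on the
composite break by ascending charged mass, which makes ranking stable
and deterministic.

## Descriptors

DBE = 1 + C + Si − (H+F+Cl+Br+I)/2 + (N+P)/2 — Si tetravalent, N and P
trivalent, halogens monovalent; DBE−O subtracts the oxygen count. Mass
defect is signed, `m − round(m)`, so typical perfluorinated anions are
negative (PFOS [M−H]⁻: −0.06978). Kendrick mass uses CF₂ as default
base (`KM = m · 50 / 49.99681`, `KMD = round(KM) − KM`), the standard
homolog unit for PFAS; the base is configurable. "Element count" is
the total atom count of the composition. Elemental ratios are NaN
(explicit missing) for carbon-free formulas.

## Spectra handling

Peak lists are centroid CSVs (m/z, intensity, S/N) read per CASI
window; the acquisition S/N ≥ 4 threshold is applied at read time
(configurable, or disabled for files without an S/N column). Windows
are trimmed to bounds ± 5 Da and stitched with duplicate retention —
the overlap keeps isotopologues of edge compounds (a sulfonate at
498.93 in a 400–500 window has its ¹⁸O isotopologue at 500.93) and
the resulting duplicate annotations are resolved at dedup, not before.
Default window set: 150–230, 230–270, 270–300, 300–1000 in 100 Da
segments, 1000–2000 (11 windows). A header-only CSV is an
acquired-but-empty window, not an error. Blank filtering runs **after**
stitching: a sample peak is flagged when a blank peak lies within the
mass tolerance and the sample/blank intensity ratio is below 10
(both configurable); flagging can remove or merely annotate, and
kept + flagged is always an exact partition of the sample.

## Synthetic data

The generator emulates the windowed acquisition end to end: spiked
compounds contribute their [M−H]⁻ peak plus every isotopologue at
theoretical relative abundance; m/z noise is Gaussian in ppm, intensity
noise multiplicative lognormal — a statistical stand-in, not a physical
FT-ICR model (no ion accumulation, space charge, resolution or phase
effects). Decoys are drawn uniformly and rejection-filtered to ≥ 5 ppm
from every suspect-list mass (monoisotopic *and* isotopologue), so the
negative set is clean by construction. Blank-overlap peaks appear in
sample and blank at equal intensity. Peaks within 5 Da of a window
bound are written into both adjacent windows, reproducing the
duplicate-retention behaviour of stitched acquisitions.

Defaults define the reference condition: 20 spiked acidic PFAS
(11 PFCAs C4–C14, 8 PFSAs C4–C11, FOSA) at intensity 10⁶ with zero
jitter and zero intensity noise (clean patterns), 200 decoys with
lognormal intensities around 10⁵, detection floor 10³, the 11 standard
windows, plus decoy suspects exercising every exclusion: two
non-ionizable perfluoroalkanes, two electropositive (basic-only)
compounds, two heteroatom-free fragment-like entries carrying a
spurious predicted acidic pKa (pKa predictors do emit values for such
compositions; these exist to exercise the fragment rule, which
otherwise would be shadowed by the pKa filter), and a PFOS potassium
salt that must collapse onto the free acid at dedup. The intensity
scales (10⁶ / 10⁵ / 10³) are plausible relative scales for spiked
standards vs. matrix background vs. detection limit in direct-infusion
FT-ICR data; they were chosen once and are config-exposed. Under the
noiseless default the pipeline must recover exactly the 20 spiked
acids with isotope score 100 — the suite asserts this, along with
byte-identical reruns at a fixed seed.

What passing these tests does **not** show about real data: the
generator has no overlapping isotope clusters from co-isolated
species, no in-source fragmentation, no ionization suppression, no
mass-dependent calibration drift, and decoys are guaranteed outside
the tolerance rather than adversarially placed. Real candidate lists
therefore need the downstream confirmation the ranking is designed to
prioritize, not replace.

## Problem sizes

Test and acceptance runs use the default synthetic scale (20 spikes +
~7 decoy suspects, 200 matrix decoys, 11 windows) and random matcher
instances of 10³ × 10³ — sizes chosen so the whole suite documents the
algorithms' behaviour while completing in seconds.

## Known limitations

* No identifier completion (InChIKey/SMILES generation); SMILES is
  used only for dot-component salt detection, with rdkit optional.
* pKa values are consumed from input columns, never predicted.
* The external-formula cross-validation hook (`OfflineFormulaHook`) is
  a stub interface; the core contains no network code by design.
* Centroid data only; no profile-mode or transient processing, no
  internal recalibration.
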