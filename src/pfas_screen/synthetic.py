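"""Ground-truthed synthetic suspect lists and direct-infusion peak lists.

The generator emulates the windowed (CASI) acquisition the screening
pipeline consumes: every spiked compound contributes its deprotonated
monoisotopic peak plus all single-substitution isotopologue peaks at
their theoretical relative abundance, optionally perturbed by a Gaussian
m/z jitter (in ppm) and a multiplicative lognormal intensity noise;
decoy matrix peaks are drawn uniformly and rejection-filtered to lie at
least 5 ppm away from every suspect-list mass (monoisotopic and
isotopologue), guaranteeing a clean negative set; blank-overlap peaks
appear in both sample and blank at comparable intensity so the blank
filter flags them.  Peaks are assigned to their CASI window and
duplicated into the neighbouring window when they fall within the
+/- 5 Da overlap, reproducing the duplicate-retention behaviour of real
stitched acquisitions.

The default suspect set is 20 spiked acidic PFAS (11 perfluorocarboxylic
acids C4-C14, 8 perfluoroalkane sulfonic acids C4-C11, and FOSA) plus
decoy suspects that exercise every exclusion rule: two non-ionizable
perfluoroalkanes, two electropositive (basic-only) compounds, two
heteroatom-free fragment-like entries carrying a spurious predicted
acidic pKa, and a potassium salt twin of PFOS that collapses onto the
free acid at deduplication.  Noise defaults are zero (clean patterns):
the noiseless limit is the reference condition under which the pipeline
must recover exactly the spiked acidic suspects with isotope score 100.

This is a statistical stand-in, not a physical FT-ICR model: no ion
accumulation, space-charge, resolution or phase effects are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pfas_screen.spectra import DEFAULT_WINDOWS, Peak, Spectrum
from pfas_screen.suspects import (
    RawSuspectRecord,
    SuspectList,
    build_suspect_list,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "default_suspect_records",
    "default_suspect_csv",
    "default_spikes",
    "simulate_dataset",
    "write_dataset",
]

#: Intensity scales chosen as realistic relative scales for spiked
#: standards vs. matrix background in direct-infusion FT-ICR data.
SPIKE_INTENSITY = 1.0e6
DECOY_INTENSITY_MEDIAN = 1.0e5
DETECTION_FLOOR = 1.0e3


def default_suspect_records() -> list[RawSuspectRecord]:
    """The built-in suspect set (see module docstring)."""
    records: list[RawSuspectRecord] = []
    # perfluorocarboxylic acids CnF(2n+1)COOH, n = 3..13
    pfca_pka = [0.7, 0.5, 0.3, 0.2, 0.1, 0.0, -0.1, -0.2, -0.2, -0.3, -0.3]
    for i, n in enumerate(range(3, 14)):
        records.append(
            RawSuspectRecord(
                id=f"PFCA_C{n + 1}",
                formula_text=f"C{n + 1}HF{2 * n + 1}O2",
                qc_level=1 + i % 5,
                pka_acidic=pfca_pka[i],
            )
        )
    # perfluoroalkane sulfonic acids CnF(2n+1)SO3H, n = 4..11
    for i, n in enumerate(range(4, 12)):
        records.append(
            RawSuspectRecord(
                id=f"PFSA_C{n}",
                formula_text=f"C{n}HF{2 * n + 1}O3S",
                qc_level=1 + i % 5,
                pka_acidic=-3.3 + 0.1 * i,
            )
        )
    # perfluorooctane sulfonamide
    records.append(
        RawSuspectRecord(
            id="FOSA",
            formula_text="C8H2F17NO2S",
            qc_level=1,
            pka_acidic=6.2,
        )
    )
    # non-ionizable perfluoroalkanes (no acidic site, no pKa)
    records.append(RawSuspectRecord(id="PF_HEXANE", formula_text="C6F14"))
    records.append(RawSuspectRecord(id="PF_PENTANE", formula_text="C5F12"))
    # electropositive: basic functional group only
    records.append(
        RawSuspectRecord(
            id="AMINE_1", formula_text="C7H6F3N", pka_basic=9.1, qc_level=3
        )
    )
    records.append(
        RawSuspectRecord(
            id="AMINE_2", formula_text="C8H6F6N2", pka_basic=8.4, qc_level=4
        )
    )
    # heteroatom-free fragment-like entries with a spurious predicted pKa
    records.append(
        RawSuspectRecord(
            id="FRAG_1", formula_text="C6HF13", pka_acidic=1.5, qc_level=5
        )
    )
    records.append(
        RawSuspectRecord(
            id="FRAG_2", formula_text="C8HF17", pka_acidic=1.2, qc_level=5
        )
    )
    # potassium salt twin of PFSA_C8 (PFOS): same anion, same charged mass
    records.append(
        RawSuspectRecord(
            id="PFSA_C8_K",
            formula_text="C8F17O3S.K",
            qc_level=2,
            pka_acidic=-3.0,
        )
    )
    return records


def default_suspect_csv(path: str | Path) -> None:
    """Write the built-in suspect set in the raw-template CSV dialect."""
    rows = [
        {
            "Molecular formula": r.formula_text,
            "id": r.id,
            "qc_level": r.qc_level,
            "pka_acidic": r.pka_acidic,
            "pka_basic": r.pka_basic,
        }
        for r in default_suspect_records()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def default_spikes(suspects: SuspectList) -> list[tuple[str, float, float]]:
    """(suspect_id, intensity, true ppm offset) for every non-salt entry."""
    return [
        (e.id, SPIKE_INTENSITY, 0.0)
        for e in suspects.entries
        if not e.is_salt
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int = 0
    spiked: list[tuple[str, float, float]] | None = None
    decoy_count: int = 200
    decoy_mass_range: tuple[float, float] = (150.0, 1000.0)
    intensity_noise_sd: float = 0.0  # lognormal sigma (relative)
    ppm_jitter_sd: float = 0.0  # Gaussian sigma in ppm
    windows: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_WINDOWS)
    )
    overlap: float = 5.0
    floor: float = DETECTION_FLOOR
    decoy_exclusion_ppm: float = 5.0
    blank_spike_count: int = 5
    blank_extra_count: int = 20

    def __post_init__(self):
        if self.ppm_jitter_sd < 0 or self.intensity_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class SimulatedDataset:
    """Windowed sample spectra, a blank spectrum, and the ground truth."""

    spectra: list[Spectrum]
    blank: Spectrum
    truth: pd.DataFrame
    suspects: SuspectList


def _perturb_mz(rng: np.random.Generator, mz: float, offset_ppm: float, sd: float) -> float:
    jitter = rng.normal(0.0, sd) if sd > 0 else 0.0
    return mz * (1.0 + (offset_ppm + jitter) * 1e-6)


def _perturb_intensity(rng: np.random.Generator, intensity: float, sd: float) -> float:
    if sd <= 0:
        return intensity
    return intensity * rng.lognormal(0.0, sd)


def simulate_dataset(
    cfg: SimulationConfig, suspects: SuspectList
) -> SimulatedDataset:
    """Generate windowed sample spectra, a blank, and a ground-truth table."""
    rng = np.random.default_rng(cfg.seed)
    spikes = cfg.spiked if cfg.spiked is not None else default_spikes(suspects)
    full_lo = min(lo for lo, _ in cfg.windows)
    full_hi = max(hi for _, hi in cfg.windows)

    # all suspect-list masses (mono + isotopologues): the decoy keep-out set
    reference_masses = suspects.table["charged_mass"].to_numpy()
    reference_masses = np.sort(reference_masses)

    truth_rows: list[dict] = []
    peaks: list[tuple[float, float, str, str]] = []  # mz, intensity, kind, owner

    for suspect_id, intensity, offset in spikes:
        entry = suspects.by_id(suspect_id)
        mono_true = entry.charged_mass
        if not any(lo <= mono_true <= hi for lo, hi in cfg.windows):
            raise ValueError(
                f"spiked mass {mono_true:.5f} of {suspect_id} lies outside "
                "every configured window"
            )
        mono_mz = _perturb_mz(rng, mono_true, offset, cfg.ppm_jitter_sd)
        mono_int = _perturb_intensity(rng, intensity, cfg.intensity_noise_sd)
        peaks.append((mono_mz, mono_int, "spike_mono", suspect_id))
        truth_rows.append(
            {
                "kind": "spike_mono",
                "suspect_id": suspect_id,
                "true_mz": mono_true,
                "mz": mono_mz,
                "intensity": mono_int,
                "true_ppm_offset": offset,
            }
        )
        for iso in entry.isotopologues:
            iso_true = mono_true + iso.mass_shift
            iso_int_theory = intensity * iso.relative_abundance
            if iso_int_theory < cfg.floor:
                continue  # below the detection floor: not acquired
            iso_mz = _perturb_mz(rng, iso_true, offset, cfg.ppm_jitter_sd)
            iso_int = _perturb_intensity(rng, iso_int_theory, cfg.intensity_noise_sd)
            peaks.append((iso_mz, iso_int, "spike_iso", f"{suspect_id}__{iso.label}"))
            truth_rows.append(
                {
                    "kind": "spike_iso",
                    "suspect_id": f"{suspect_id}__{iso.label}",
                    "true_mz": iso_true,
                    "mz": iso_mz,
                    "intensity": iso_int,
                    "true_ppm_offset": offset,
                }
            )

    def far_from_suspects(mz: float) -> bool:
        i = np.searchsorted(reference_masses, mz)
        for j in (i - 1, i):
            if 0 <= j < len(reference_masses):
                if abs(mz - reference_masses[j]) / reference_masses[j] * 1e6 < cfg.decoy_exclusion_ppm:
                    return False
        return True

    lo_m, hi_m = cfg.decoy_mass_range
    n_decoy = 0
    while n_decoy < cfg.decoy_count:
        mz = float(rng.uniform(lo_m, hi_m))
        if not far_from_suspects(mz):
            continue
        intensity = max(
            cfg.floor, float(rng.lognormal(np.log(DECOY_INTENSITY_MEDIAN), 0.5))
        )
        peaks.append((mz, intensity, "decoy", f"D{n_decoy:04d}"))
        truth_rows.append(
            {
                "kind": "decoy",
                "suspect_id": f"D{n_decoy:04d}",
                "true_mz": mz,
                "mz": mz,
                "intensity": intensity,
                "true_ppm_offset": np.nan,
            }
        )
        n_decoy += 1

    # blank-overlap peaks: present in sample and blank at equal intensity,
    # so the sample/blank ratio (1) is far below any sensible ratio_min
    blank_peaks: list[tuple[float, float]] = []
    n_blank = 0
    while n_blank < cfg.blank_spike_count:
        mz = float(rng.uniform(lo_m, hi_m))
        if not far_from_suspects(mz):
            continue
        intensity = max(
            cfg.floor, float(rng.lognormal(np.log(DECOY_INTENSITY_MEDIAN), 0.5))
        )
        peaks.append((mz, intensity, "blank_overlap", f"B{n_blank:02d}"))
        blank_peaks.append((mz, intensity))
        truth_rows.append(
            {
                "kind": "blank_overlap",
                "suspect_id": f"B{n_blank:02d}",
                "true_mz": mz,
                "mz": mz,
                "intensity": intensity,
                "true_ppm_offset": np.nan,
            }
        )
        n_blank += 1
    # blank-only peaks (must not flag anything in the sample)
    n_extra = 0
    while n_extra < cfg.blank_extra_count:
        mz = float(rng.uniform(lo_m, hi_m))
        if not far_from_suspects(mz):
            continue
        blank_peaks.append(
            (mz, max(cfg.floor, float(rng.lognormal(np.log(DECOY_INTENSITY_MEDIAN), 0.5))))
        )
        n_extra += 1

    # window assignment with duplicate retention inside the +/- overlap
    spectra: list[Spectrum] = []
    for lo, hi in cfg.windows:
        window_peaks = [
            Peak(mz, inten, snr=4.0 * inten / cfg.floor)
            for mz, inten, _, _ in peaks
            if lo - cfg.overlap <= mz <= hi + cfg.overlap
        ]
        spectra.append(
            Spectrum(
                peaks=window_peaks,
                window_lo=lo,
                window_hi=hi,
                label=f"{lo:g}-{hi:g}",
            )
        )

    blank = Spectrum(
        peaks=[
            Peak(mz, inten, snr=4.0 * inten / cfg.floor)
            for mz, inten in blank_peaks
        ],
        window_lo=full_lo,
        window_hi=full_hi,
        label="blank",
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "suspect_id", "true_mz", "mz", "intensity", "true_ppm_offset"],
    ).sort_values(["kind", "mz"], kind="stable").reset_index(drop=True)
    return SimulatedDataset(spectra=spectra, blank=blank, truth=truth, suspects=suspects)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the dataset in the CSV peak-list dialect the reader consumes.

    One ``window_<lo>-<hi>.csv`` per CASI window, ``blank.csv``, and
    ``ground_truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in dataset.spectra:
        pd.DataFrame(
            [(p.mz, p.intensity, p.snr) for p in s.peaks],
            columns=["m/z", "intensity", "S/N"],
        ).to_csv(out / f"window_{s.label}.csv", index=False)
    pd.DataFrame(
        [(p.mz, p.intensity, p.snr) for p in dataset.blank.peaks],
        columns=["m/z", "intensity", "S/N"],
    ).to_csv(out / "blank.csv", index=False)
    dataset.truth.to_csv(out / "ground_truth.csv", index=False)


def default_dataset(seed: int = 0, **overrides) -> SimulatedDataset:
    """Build the default suspect list and simulate under default conditions."""
    suspects = build_suspect_list(default_suspect_records())
    cfg = SimulationConfig(seed=seed, **overrides)
    return simulate_dataset(cfg, suspects)
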