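"""Calibrated centroid peak lists from windowed direct-infusion acquisition.

Spectra are acquired per quadrupole-isolation (CASI) window and stitched:
each window is trimmed with a +/- 5 Da overlap so that isotopologues of a
compound sitting at a window edge are not lost, then all windows are
concatenated with provenance tags.  Duplicate peaks arising from the
overlap are retained here on purpose — deduplication is the first step of
the downstream candidate evaluation, where the duplicate with the higher
S/N survives.

The minimum retained intensity is tracked per window; it is the
detectability floor used by the isotope-scoring stage to decide which
isotopologues *should* have been observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "Spectrum",
    "MergedPeakList",
    "DEFAULT_WINDOWS",
    "read_peaklist",
    "trim_to_window",
    "merge_windows",
    "blank_filter",
]

#: Default CASI window bounds in Da: 150-230, 230-270, 270-300,
#: 300-1000 in 100 Da segments, 1000-2000 (11 windows).
DEFAULT_WINDOW_EDGES = [150, 230, 270, 300, 400, 500, 600, 700, 800, 900, 1000, 2000]
DEFAULT_WINDOWS = list(zip(DEFAULT_WINDOW_EDGES[:-1], DEFAULT_WINDOW_EDGES[1:]))


@dataclass(frozen=True)
class Peak:
    """One centroid peak: m/z (Da), intensity (counts), S/N ratio."""

    mz: float
    intensity: float
    snr: float = 0.0


@dataclass
class Spectrum:
    """A peak list from one CASI window, sorted ascending by m/z."""

    peaks: list[Peak]
    window_lo: float
    window_hi: float
    label: str = ""
    row_errors: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.window_lo >= self.window_hi:
            raise ValueError(
                f"window_lo {self.window_lo} must be < window_hi {self.window_hi}"
            )
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)


class MergedPeakList:
    """Stitched peak list across windows, with provenance per peak.

    Backed by a DataFrame with columns ``mz, intensity, snr, window``,
    sorted by m/z (stable, so provenance order is preserved among equal
    masses).  ``floor_by_window`` maps window label to the smallest
    retained intensity in that window.
    """

    def __init__(self, df: pd.DataFrame, floor_by_window: dict[str, float]):
        self.df = df.sort_values("mz", kind="stable").reset_index(drop=True)
        self.floor_by_window = dict(floor_by_window)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mz(self) -> np.ndarray:
        return self.df["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.df["intensity"].to_numpy()

    @property
    def snr(self) -> np.ndarray:
        return self.df["snr"].to_numpy()

    @property
    def window(self) -> pd.Series:
        return self.df["window"]

    @property
    def min_detected_intensity(self) -> float:
        """Global floor: the smallest retained intensity across windows."""
        if not self.floor_by_window:
            return float("nan")
        return min(self.floor_by_window.values())

    def floor_for(self, window_label: str) -> float:
        return self.floor_by_window.get(window_label, self.min_detected_intensity)


def read_peaklist(
    path: str | Path,
    window: tuple[float, float],
    label: str | None = None,
    snr_min: float | None = 4.0,
    mz_col: str = "m/z",
    intensity_col: str = "intensity",
    snr_col: str = "S/N",
) -> Spectrum:
    """Read one CSV peak list for a CASI window.

    Applies the S/N >= ``snr_min`` acquisition threshold (default 4; pass
    ``None`` to disable, e.g. for files without an S/N column).  Rows with
    non-numeric or non-positive values are collected in
    ``Spectrum.row_errors`` rather than aborting the read.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty peak list: {path}") from None
    for col in (mz_col, intensity_col):
        if col not in df.columns:
            raise ValueError(f"peak list {path} lacks column {col!r}")
    has_snr = snr_col in df.columns
    if snr_min is not None and not has_snr:
        raise ValueError(
            f"peak list {path} lacks S/N column {snr_col!r}; "
            "pass snr_min=None to read it anyway"
        )
    peaks: list[Peak] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            mz = float(row[mz_col])
            intensity = float(row[intensity_col])
            snr = float(row[snr_col]) if has_snr else 0.0
        except (TypeError, ValueError):
            errors.append(f"row {i}: non-numeric value")
            continue
        if mz <= 0 or intensity <= 0 or snr < 0:
            errors.append(f"row {i}: non-positive mz/intensity or negative S/N")
            continue
        if snr_min is not None and snr < snr_min:
            continue
        peaks.append(Peak(mz, intensity, snr))
    return Spectrum(
        peaks=peaks,
        window_lo=window[0],
        window_hi=window[1],
        label=label or f"{window[0]:g}-{window[1]:g}",
        row_errors=errors,
    )


def trim_to_window(s: Spectrum, overlap: float = 5.0) -> Spectrum:
    """Keep peaks with ``window_lo - overlap <= mz <= window_hi + overlap``.

    The overlap (default +/- 5 Da) keeps isotopologues of edge compounds:
    e.g. a sulfonate monoisotopic peak just below a window boundary has
    its 18O isotopologue ~2 Da above it, in the next window.
    """
    lo, hi = s.window_lo - overlap, s.window_hi + overlap
    return Spectrum(
        peaks=[p for p in s.peaks if lo <= p.mz <= hi],
        window_lo=s.window_lo,
        window_hi=s.window_hi,
        label=s.label,
        row_errors=list(s.row_errors),
    )


def merge_windows(spectra: Sequence[Spectrum]) -> MergedPeakList:
    """Stitch windowed spectra into one provenance-tagged peak list.

    Peaks duplicated by the window overlap are retained (and tagged with
    their source window); the per-window minimum retained intensity is
    recorded as the detectability floor for isotope scoring.
    """
    if not spectra:
        raise ValueError("merge_windows needs at least one spectrum")
    rows = []
    floors: dict[str, float] = {}
    for s in spectra:
        for p in s.peaks:
            rows.append((p.mz, p.intensity, p.snr, s.label))
        if s.peaks:
            floors[s.label] = min(p.intensity for p in s.peaks)
    df = pd.DataFrame(rows, columns=["mz", "intensity", "snr", "window"])
    return MergedPeakList(df, floors)


def blank_filter(
    sample: MergedPeakList,
    blank: MergedPeakList,
    ppm_tol: float = 1.5,
    ratio_min: float = 10.0,
    remove: bool = True,
) -> tuple[MergedPeakList, MergedPeakList]:
    """Flag sample peaks that are explainable by the blank.

    A sample peak is flagged when a blank peak lies within ``ppm_tol`` of
    its m/z *and* the sample/blank intensity ratio is below ``ratio_min``.
    Returns ``(kept, flagged)``; with ``remove=False`` the kept list is
    the full sample (flagging is annotation-only) but the partition is
    still reported.  kept + flagged is always a partition of the sample.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if ratio_min < 1:
        raise ValueError("ratio_min must be >= 1")
    smz = sample.mz
    flagged_mask = np.zeros(len(smz), dtype=bool)
    if len(blank) and len(smz):
        bmz = blank.mz
        bint = blank.intensity
        tol = smz * ppm_tol * 1e-6
        lo = np.searchsorted(bmz, smz - tol, side="left")
        hi = np.searchsorted(bmz, smz + tol, side="right")
        sint = sample.intensity
        for i in range(len(smz)):
            if lo[i] == hi[i]:
                continue
            # max blank intensity within tolerance decides the ratio
            if sint[i] / bint[lo[i]:hi[i]].max() < ratio_min:
                flagged_mask[i] = True
    flagged = MergedPeakList(sample.df[flagged_mask], sample.floor_by_window)
    if remove:
        kept = MergedPeakList(sample.df[~flagged_mask], sample.floor_by_window)
    else:
        kept = MergedPeakList(sample.df, sample.floor_by_window)
    return kept, flagged
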