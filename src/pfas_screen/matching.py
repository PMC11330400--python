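"""Distance-based suspect matching.

Each suspect's charged (deprotonated) mass is searched against the merged
measured m/z list: the k nearest measured values by absolute mass
distance are paired with the suspect, and pairs within the ppm tolerance
become candidate annotations.  In one dimension the Euclidean distance
reduces to the absolute difference, so the k-neighbour search is a binary
search on the sorted m/z array.  One measured peak may carry several
suspect annotations (near-isobaric suspects closer than the tolerance are
all retained as distinct candidates); deduplication of one suspect seen
in two overlapping windows happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pfas_screen.spectra import MergedPeakList, Peak
from pfas_screen.suspects import SuspectEntry

__all__ = ["CandidateMatch", "ppm_error", "match_suspects", "matches_to_frame"]


@dataclass
class CandidateMatch:
    """One (measured peak, suspect) pair within the mass tolerance."""

    suspect_id: str
    peak: Peak
    window: str
    theoretical_mz: float
    ppm_error: float


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed mass error in ppm: (measured - theoretical)/theoretical * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (measured - theoretical) / theoretical * 1e6


def match_suspects(
    peaks: MergedPeakList,
    suspects: Sequence[SuspectEntry],
    k: int = 10,
    tol_ppm: float = 1.5,
) -> list[CandidateMatch]:
    """Match suspect charged masses against measured m/z values.

    For each suspect the ``k`` nearest measured m/z (absolute Da
    distance, ties kept on both sides) are examined and every pair with
    ``|ppm_error| <= tol_ppm`` becomes a :class:`CandidateMatch`.  Since
    the tolerance alone decides acceptance, ``k`` only caps the number of
    annotations a single suspect can collect.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    mz = peaks.mz
    n = len(mz)
    out: list[CandidateMatch] = []
    if n == 0:
        return out
    df = peaks.df
    for suspect in suspects:
        target = suspect.charged_mass
        pos = int(np.searchsorted(mz, target))
        # widen symmetrically to the k nearest, keeping distance ties
        lo, hi = pos, pos  # candidate range [lo, hi)
        while hi - lo < k and (lo > 0 or hi < n):
            d_left = target - mz[lo - 1] if lo > 0 else np.inf
            d_right = mz[hi] - target if hi < n else np.inf
            if d_left <= d_right:
                lo -= 1
            else:
                hi += 1
        # include ties at the outer boundary (identical distance)
        if hi - lo == k:
            outer = max(target - mz[lo], mz[hi - 1] - target)
            while lo > 0 and target - mz[lo - 1] == outer:
                lo -= 1
            while hi < n and mz[hi] - target == outer:
                hi += 1
        for i in range(lo, hi):
            err = ppm_error(mz[i], target)
            if abs(err) <= tol_ppm:
                row = df.iloc[i]
                out.append(
                    CandidateMatch(
                        suspect_id=suspect.id,
                        peak=Peak(
                            float(row["mz"]),
                            float(row["intensity"]),
                            float(row["snr"]),
                        ),
                        window=str(row["window"]),
                        theoretical_mz=target,
                        ppm_error=err,
                    )
                )
    return out


def matches_to_frame(matches: Sequence[CandidateMatch]) -> pd.DataFrame:
    """Candidate table: one row per (suspect, peak) annotation."""
    return pd.DataFrame(
        [
            {
                "suspect_id": m.suspect_id,
                "measured_mz": m.peak.mz,
                "theoretical_mz": m.theoretical_mz,
                "ppm_error": m.ppm_error,
                "intensity": m.peak.intensity,
                "snr": m.peak.snr,
                "window": m.window,
            }
            for m in matches
        ],
        columns=[
            "suspect_id",
            "measured_mz",
            "theoretical_mz",
            "ppm_error",
            "intensity",
            "snr",
            "window",
        ],
    )
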