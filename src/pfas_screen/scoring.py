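"""Isotopologue-pattern validation of candidate annotations.

For a matched candidate, the theoretical pattern is anchored on the
*measured* monoisotopic peak: each isotopologue is predicted at the
measured m/z plus the heavy-light isotope mass shift, with intensity
equal to the measured monoisotopic intensity times the isotopologue's
relative abundance.  An isotopologue is *expected* when its predicted
intensity is at or above the detection floor (the minimum retained
intensity of the window it falls in).

Each expected isotopologue is compared with the nearest measured peak
within the ppm tolerance, in two dimensions chosen to be scale-free: the
mass deviation in ppm and the intensity deviation as a relative
percentage.  The Euclidean distance d over these two coordinates is
converted to a similarity 1/(1+d), weighted by predicted intensity
(normalized to sum 1 over the scored isotopologues), and summed to a
0-100 isotope score.  An expected-but-missing isotopologue contributes
similarity 0 at full weight, so any deviation from the simulated pattern
lowers the score.  Candidates with at least one expected isotopologue are
level L-4 (scored); candidates whose isotopologues are all below the
floor cannot be validated and are level L-5 (accurate mass only, no
score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pfas_screen.matching import CandidateMatch, ppm_error
from pfas_screen.spectra import MergedPeakList
from pfas_screen.suspects import SuspectEntry

__all__ = [
    "IsotopologueObservation",
    "IsotopeScoreResult",
    "L4",
    "L5",
    "predict_pattern",
    "score_candidate",
    "score_all",
]

L4 = "L4"
L5 = "L5"


@dataclass
class IsotopologueObservation:
    """One isotopologue of a candidate: prediction, match, and similarity."""

    label: str
    predicted_mz: float
    predicted_intensity: float
    expected: bool
    measured_mz: float | None = None
    measured_intensity: float | None = None
    delta_ppm: float = math.nan
    delta_rel_pct: float = math.nan
    d: float = math.nan
    similarity: float = math.nan
    weight: float = 0.0


@dataclass
class IsotopeScoreResult:
    """Isotope-score outcome for one candidate annotation."""

    candidate: CandidateMatch
    level: str
    score: float | None
    observations: list[IsotopologueObservation]


def predict_pattern(
    candidate: CandidateMatch,
    suspect: SuspectEntry,
    floor: float,
) -> list[IsotopologueObservation]:
    """Predict the isotopologue pattern anchored on the measured peak.

    ``floor`` is the minimum detectable intensity; isotopologues
    predicted below it are marked ``expected=False`` and carry no weight
    in scoring (they could not have been observed).
    """
    if candidate.peak.intensity <= 0:
        raise ValueError("candidate peak intensity must be positive")
    out = []
    for iso in suspect.isotopologues:
        predicted_intensity = candidate.peak.intensity * iso.relative_abundance
        out.append(
            IsotopologueObservation(
                label=iso.label,
                predicted_mz=candidate.peak.mz + iso.mass_shift,
                predicted_intensity=predicted_intensity,
                expected=predicted_intensity >= floor,
            )
        )
    return out


def _nearest_peak(
    peaks: MergedPeakList, mz_pred: float, tol_ppm: float
) -> tuple[float, float] | None:
    """Nearest peak to mz_pred within tol_ppm.

    Ties on |delta ppm| break toward the higher-intensity peak.
    """
    mz = peaks.mz
    if len(mz) == 0:
        return None
    tol = mz_pred * tol_ppm * 1e-6
    lo = int(np.searchsorted(mz, mz_pred - tol, side="left"))
    hi = int(np.searchsorted(mz, mz_pred + tol, side="right"))
    if lo == hi:
        return None
    window_mz = mz[lo:hi]
    window_int = peaks.intensity[lo:hi]
    dev = np.abs(window_mz - mz_pred)
    best = np.flatnonzero(dev == dev.min())
    if len(best) > 1:
        best = best[np.argmax(window_int[best])]
    else:
        best = best[0]
    return float(window_mz[best]), float(window_int[best])


def score_candidate(
    observations: Sequence[IsotopologueObservation],
    peaks: MergedPeakList,
    tol_ppm: float = 1.5,
    candidate: CandidateMatch | None = None,
) -> IsotopeScoreResult:
    """Score one candidate's isotopologue pattern against measured peaks.

    Sub-floor isotopologues are excluded and the intensity weights are
    renormalized over the remaining (expected) ones; an expected
    isotopologue with no peak within ``tol_ppm`` keeps its full weight at
    similarity 0.  With no expected isotopologue at all, the candidate is
    L-5 and carries no score.
    """
    observations = list(observations)
    expected = [o for o in observations if o.expected]
    if not expected:
        return IsotopeScoreResult(
            candidate=candidate, level=L5, score=None, observations=observations
        )
    total_predicted = sum(o.predicted_intensity for o in expected)
    score = 0.0
    for obs in expected:
        obs.weight = obs.predicted_intensity / total_predicted
        found = _nearest_peak(peaks, obs.predicted_mz, tol_ppm)
        if found is None:
            obs.similarity = 0.0
            obs.d = math.inf
        else:
            obs.measured_mz, obs.measured_intensity = found
            obs.delta_ppm = ppm_error(obs.measured_mz, obs.predicted_mz)
            obs.delta_rel_pct = (
                abs(obs.measured_intensity - obs.predicted_intensity)
                / obs.predicted_intensity
                * 100.0
            )
            obs.d = math.hypot(obs.delta_ppm, obs.delta_rel_pct)
            obs.similarity = 1.0 / (1.0 + obs.d)
        score += obs.similarity * obs.weight
    return IsotopeScoreResult(
        candidate=candidate,
        level=L4,
        score=score * 100.0,
        observations=observations,
    )


def score_all(
    matches: Sequence[CandidateMatch],
    suspects_by_id: dict[str, SuspectEntry],
    peaks: MergedPeakList,
    tol_ppm: float = 1.5,
) -> list[IsotopeScoreResult]:
    """Predict and score every candidate, using its window's floor."""
    results = []
    for m in matches:
        suspect = suspects_by_id[m.suspect_id]
        floor = peaks.floor_for(m.window)
        pattern = predict_pattern(m, suspect, floor)
        results.append(score_candidate(pattern, peaks, tol_ppm, candidate=m))
    return results
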