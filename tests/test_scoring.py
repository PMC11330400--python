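"""Weighted Euclidean isotope score: closed forms, oracle, monotonicity."""

import math

import numpy as np
import pandas as pd
import pytest

from pfas_screen.matching import CandidateMatch
from pfas_screen.scoring import (
    L4,
    L5,
    IsotopologueObservation,
    predict_pattern,
    score_candidate,
)
from pfas_screen.spectra import MergedPeakList, Peak
from pfas_screen.suspects import RawSuspectRecord, build_suspect_list


def _peaklist(rows):
    """rows: (mz, intensity)"""
    df = pd.DataFrame(
        [(mz, inten, 10.0, "w") for mz, inten in sorted(rows)],
        columns=["mz", "intensity", "snr", "window"],
    )
    floor = df["intensity"].min() if len(df) else 1.0
    return MergedPeakList(df, {"w": float(floor)})


def _obs(predicted, floor=0.0):
    """predicted: list of (mz, intensity)"""
    return [
        IsotopologueObservation(
            label=f"i{j}",
            predicted_mz=mz,
            predicted_intensity=inten,
            expected=inten >= floor,
        )
        for j, (mz, inten) in enumerate(predicted)
    ]


def naive_score(deltas, weights_raw):
    """Straight-line independent oracle for the score arithmetic.

    deltas: per expected isotopologue either None (missing) or
    (delta_ppm, delta_rel_pct); weights_raw: predicted intensities.
    """
    total = sum(weights_raw)
    score = 0.0
    for delta, w in zip(deltas, weights_raw):
        if delta is None:
            sim = 0.0
        else:
            d = math.sqrt(delta[0] ** 2 + delta[1] ** 2)
            sim = 1.0 / (1.0 + d)
        score += sim * (w / total)
    return score * 100.0


def test_perfect_pattern_scores_100():
    predicted = [(500.0, 1e5), (502.0, 4e4), (504.0, 5e3)]
    result = score_candidate(_obs(predicted), _peaklist(predicted))
    assert result.level == L4
    assert result.score == pytest.approx(100.0, rel=1e-12)
    assert sum(o.weight for o in result.observations) == pytest.approx(1.0)


def test_single_isotopologue_d5_scores_one_sixth():
    # delta_ppm = 3, delta_rel_pct = 4 -> d = 5 -> similarity 1/6
    pred_mz, pred_int = 500.0, 1e5
    meas_mz = pred_mz * (1 + 3e-6)
    meas_int = pred_int * 1.04
    result = score_candidate(
        _obs([(pred_mz, pred_int)]), _peaklist([(meas_mz, meas_int)]), tol_ppm=5.0
    )
    assert result.score == pytest.approx(100.0 / 6.0, rel=1e-9)


def test_missing_isotopologue_keeps_full_weight():
    # weights 0.8 / 0.2; the low-abundance one is absent -> score 80
    predicted = [(500.0, 8e4), (502.0, 2e4)]
    measured = [(500.0, 8e4)]
    result = score_candidate(_obs(predicted), _peaklist(measured))
    assert result.score == pytest.approx(80.0, rel=1e-9)


def test_all_below_floor_is_L5_without_score():
    observations = _obs([(500.0, 1e2), (502.0, 2e2)], floor=1e3)
    result = score_candidate(observations, _peaklist([(500.0, 1e2)]))
    assert result.level == L5
    assert result.score is None


def test_subfloor_isotopologues_renormalize_weights():
    # one expected (8e4) and one sub-floor (2e2, floor 1e3): the sub-floor
    # observation is excluded and the expected one carries weight 1
    observations = _obs([(500.0, 8e4), (502.0, 2e2)], floor=1e3)
    result = score_candidate(observations, _peaklist([(500.0, 8e4)]))
    assert result.score == pytest.approx(100.0)
    scored = [o for o in result.observations if o.expected]
    assert [o.weight for o in scored] == [1.0]


def test_agrees_with_straight_line_oracle_on_random_inputs():
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = rng.integers(1, 5)
        pred = [(500.0 + 3 * j, float(rng.uniform(1e4, 1e6))) for j in range(n)]
        deltas, measured = [], []
        for mz, inten in pred:
            if rng.random() < 0.2:
                deltas.append(None)  # missing
                continue
            dppm = float(rng.uniform(0, 1.2))
            drel = float(rng.uniform(0, 80))
            deltas.append((dppm, drel))
            measured.append((mz * (1 + dppm * 1e-6), inten * (1 + drel / 100)))
        result = score_candidate(_obs(pred), _peaklist(measured), tol_ppm=1.5)
        expected = naive_score(deltas, [p[1] for p in pred])
        assert result.score == pytest.approx(expected, rel=1e-9)


def test_monotone_decay_under_perturbation():
    """Increasing any |delta| strictly lowers the score (1000 random cases)."""
    rng = np.random.default_rng(5)
    for _ in range(1000):
        n = int(rng.integers(1, 4))
        pred = [(500.0 + 4 * j, float(rng.uniform(1e4, 1e6))) for j in range(n)]
        deltas = [
            (float(rng.uniform(0, 0.5)), float(rng.uniform(0, 40)))
            for _ in range(n)
        ]

        def run(ds):
            measured = [
                (mz * (1 + dp * 1e-6), inten * (1 + dr / 100))
                for (mz, inten), (dp, dr) in zip(pred, ds)
            ]
            return score_candidate(_obs(pred), _peaklist(measured), tol_ppm=1.5).score

        base = run(deltas)
        j = int(rng.integers(0, n))
        worse = list(deltas)
        if rng.random() < 0.5:
            worse[j] = (worse[j][0] + 0.3, worse[j][1])
        else:
            worse[j] = (worse[j][0], worse[j][1] + 10.0)
        assert run(worse) < base


def test_removing_low_similarity_observation_raises_score():
    pred = [(500.0, 8e4), (502.0, 2e4)]
    measured = [(500.0, 8e4), (502.0 * (1 + 1e-6), 2e4 * 1.5)]  # second is poor
    with_both = score_candidate(_obs(pred), _peaklist(measured), tol_ppm=1.5)
    only_good = score_candidate(_obs(pred[:1]), _peaklist(measured[:1]), tol_ppm=1.5)
    assert only_good.score > with_both.score


def test_predict_pattern_pfos_18O():
    sl = build_suspect_list(
        [RawSuspectRecord(id="PFOS", formula_text="C8HF17O3S", pka_acidic=-3.3)]
    )
    entry = sl.by_id("PFOS")
    match = CandidateMatch(
        suspect_id="PFOS",
        peak=Peak(498.93022, 1e6, 100.0),
        window="400-500",
        theoretical_mz=entry.charged_mass,
        ppm_error=0.0,
    )
    pattern = predict_pattern(match, entry, floor=1e3)
    by_label = {o.label: o for o in pattern}
    assert by_label["18O"].predicted_mz == pytest.approx(500.93446, abs=1e-5)
    assert by_label["13C"].predicted_intensity == pytest.approx(
        1e6 * 8 * 0.0107 / 0.9893, rel=1e-3
    )
    assert all(o.expected for o in pattern)
    # floor above every prediction: nothing expected
    pattern_hi = predict_pattern(match, entry, floor=1e9)
    assert not any(o.expected for o in pattern_hi)


def test_nearest_peak_tie_breaks():
    # two peaks at equal |delta ppm|: the more intense one is chosen
    pred = [(500.0, 1e5)]
    eps = 500.0 * 5e-7
    measured = [(500.0 - eps, 5e4), (500.0 + eps, 1e5)]
    result = score_candidate(_obs(pred), _peaklist(measured), tol_ppm=1.5)
    (obs,) = [o for o in result.observations if o.expected]
    assert obs.measured_intensity == 1e5
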