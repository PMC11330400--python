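"""Candidate funnel: dedup, thresholds, exclusions, composite ranking."""

import pytest

from pfas_screen.matching import CandidateMatch
from pfas_screen.ranking import (
    Candidate,
    FunnelReport,
    composite_rank,
    dedup,
    fragment_exclusion,
    funnel_report,
    pka_exclusion,
    similarity_threshold,
    OfflineFormulaHook,
)
from pfas_screen.scoring import L4, L5, IsotopeScoreResult
from pfas_screen.spectra import Peak
from pfas_screen.suspects import RawSuspectRecord, build_suspect_list


def _candidate(
    formula="C8HF17O3S",
    sid="S",
    ppm=0.0,
    snr=30.0,
    score=100.0,
    level=L4,
    qc=1,
    pka_acidic=-3.3,
    pka_basic=None,
    window="w",
):
    sl = build_suspect_list(
        [
            RawSuspectRecord(
                id=sid,
                formula_text=formula,
                qc_level=qc,
                pka_acidic=pka_acidic,
                pka_basic=pka_basic,
            )
        ]
    )
    suspect = sl.entries[0]
    match = CandidateMatch(
        suspect_id=sid,
        peak=Peak(suspect.charged_mass * (1 + ppm * 1e-6), 1e6, snr),
        window=window,
        theoretical_mz=suspect.charged_mass,
        ppm_error=ppm,
    )
    result = IsotopeScoreResult(
        candidate=match,
        level=level,
        score=score if level == L4 else None,
        observations=[],
    )
    return Candidate(suspect=suspect, match=match, result=result)


def test_dedup_salt_and_acid_twins_keep_higher_snr():
    acid = _candidate(formula="C8HF17O3S", sid="acid", snr=30.0)
    salt = _candidate(formula="C8F17O3S.K", sid="salt", snr=12.0)
    assert salt.charged_mass == acid.charged_mass
    kept = dedup([acid, salt])
    assert [c.suspect.id for c in kept] == ["acid"]


def test_dedup_window_twins_keep_higher_snr():
    a = _candidate(sid="x", snr=12.0, window="400-500")
    b = _candidate(sid="x", snr=30.0, window="500-600")
    kept = dedup([a, b])
    assert len(kept) == 1 and kept[0].snr == 30.0


def test_dedup_identity_without_duplicates():
    a = _candidate(formula="C4HF7O2", sid="a")
    b = _candidate(formula="C8HF17O3S", sid="b")
    assert dedup([a, b]) == [a, b]


def test_similarity_threshold():
    cands = [
        _candidate(sid="a", score=100.0),
        _candidate(sid="b", score=80.0),
        _candidate(sid="c", score=74.9),
        _candidate(sid="d", level=L5, score=None, pka_acidic=None),
    ]
    kept = similarity_threshold(cands, 75.0)
    assert [c.suspect.id for c in kept] == ["a", "b", "d"]  # L5 passes
    assert similarity_threshold(cands, 0.0) == cands


def test_pka_exclusion_partitions_by_reason():
    acid = _candidate(sid="acid", pka_acidic=-3.0)
    frag = _candidate(formula="C6F14", sid="hexane", pka_acidic=None)
    basic = _candidate(formula="C7H6F3N", sid="amine", pka_acidic=None,
                       pka_basic=9.1)
    kept, non_ion, electro = pka_exclusion([acid, frag, basic])
    assert [c.suspect.id for c in kept] == ["acid"]
    assert [c.suspect.id for c in non_ion] == ["hexane"]
    assert [c.suspect.id for c in electro] == ["amine"]
    assert len(kept) + len(non_ion) + len(electro) == 3


def test_fragment_exclusion_removes_heteroatom_free():
    pfos = _candidate(sid="pfos")
    frag = _candidate(formula="C6HF13", sid="frag", pka_acidic=1.5)
    assert [c.suspect.id for c in fragment_exclusion([pfos, frag])] == ["pfos"]
    assert fragment_exclusion([]) == []


def test_composite_rank_minmax_arithmetic():
    cands = [
        _candidate(formula="C4HF7O2", sid="a", ppm=0.1, qc=1, pka_acidic=-3.0),
        _candidate(formula="C5HF9O2", sid="b", ppm=0.5, qc=3, pka_acidic=0.0),
        _candidate(formula="C6HF11O2", sid="c", ppm=1.0, qc=5, pka_acidic=3.0),
    ]
    ranked = composite_rank(cands)
    by_id = {r.candidate.suspect.id: r for r in ranked}
    assert by_id["a"].composite == pytest.approx(0.0)
    assert by_id["b"].composite == pytest.approx(0.5, abs=0.06)  # ppm norm 4/9
    assert by_id["c"].composite == pytest.approx(1.0)
    assert [r.candidate.suspect.id for r in ranked] == ["a", "b", "c"]
    assert [r.rank for r in ranked] == [1, 2, 3]


def test_composite_rank_qc_endpoints_and_degenerate_minmax():
    lone = composite_rank([_candidate(sid="only", ppm=0.7, qc=1)])
    assert lone[0].norm_mass_acc == 0.0  # degenerate min=max maps to best
    assert lone[0].norm_qc == 0.0
    qc5 = composite_rank([_candidate(sid="q5", qc=5)])[0]
    assert qc5.norm_qc == 1.0


def test_composite_rank_tie_break_by_mass():
    small = _candidate(formula="C4HF7O2", sid="small", ppm=0.3, qc=3)
    big = _candidate(formula="C8HF17O3S", sid="big", ppm=0.3, qc=3)
    ranked = composite_rank([big, small])
    assert [r.candidate.suspect.id for r in ranked] == ["small", "big"]


def test_composite_rank_affine_invariance_of_minmax():
    cands = [
        _candidate(formula="C4HF7O2", sid="a", ppm=0.1, qc=1, pka_acidic=-3.0),
        _candidate(formula="C5HF9O2", sid="b", ppm=0.5, qc=3, pka_acidic=0.0),
        _candidate(formula="C6HF11O2", sid="c", ppm=1.0, qc=5, pka_acidic=3.0),
    ]
    base = {r.candidate.suspect.id: r.norm_pka for r in composite_rank(cands)}
    rescaled = [
        _candidate(formula=c.suspect.neutral_formula.hill(), sid=c.suspect.id,
                   ppm=c.match.ppm_error, qc=c.suspect.qc_level,
                   pka_acidic=2.0 * c.suspect.pka_acidic + 7.0)
        for c in cands
    ]
    shifted = {r.candidate.suspect.id: r.norm_pka for r in composite_rank(rescaled)}
    for sid in base:
        assert shifted[sid] == pytest.approx(base[sid], abs=1e-12)


def test_missing_pka_among_kept_warns_and_gets_worst_norm():
    cands = [
        _candidate(formula="C4HF7O2", sid="a", pka_acidic=-3.0),
        _candidate(formula="C8HF17O3S", sid="b", pka_acidic=None),
    ]
    with pytest.warns(UserWarning, match="pKa"):
        ranked = composite_rank(cands)
    assert {r.candidate.suspect.id: r.norm_pka for r in ranked}["b"] == 1.0


def test_funnel_checker_validates_published_style_counts():
    # candidate funnel: 238 matched, -48 duplicates, -7 low score -> 183,
    # -64 non-ionizable, -35 electropositive -> 84 final
    report = funnel_report(
        [
            ("matched", 238, 238, "within 1.5 ppm"),
            ("dedup", 238, 190, "duplicate annotations"),
            ("similarity_threshold", 190, 183, "score < 75"),
            ("pka_non_ionizable", 183, 119, "no ionizable site"),
            ("pka_electropositive", 119, 84, "positive-mode only"),
        ]
    )
    assert report.stages[-1]["n_out"] == 84
    assert 183 - 64 - 35 == 84  # the arithmetic the checker enforces


def test_funnel_checker_rejects_inconsistent_bookkeeping():
    report = FunnelReport()
    report.add("a", 10, 8)
    report.stages[0]["n_removed"] = 5  # corrupt: 10 - 5 != 8
    with pytest.raises(RuntimeError):
        report.check()
    disc = FunnelReport()
    disc.add("a", 10, 8)
    disc.add("b", 9, 9)  # discontinuity: starts with 9, previous left 8
    with pytest.raises(RuntimeError):
        disc.check()


def test_funnel_empty_input_all_zero():
    report = funnel_report([("dedup", 0, 0), ("score", 0, 0)])
    assert all(s["n_removed"] == 0 for s in report.stages)


def test_offline_formula_hook_stub_returns_nothing():
    assert OfflineFormulaHook().query(498.93022, 1.5) == []
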