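"""Candidate reduction and ranking.

The matched-and-scored candidate list is funnelled to a final ranked
table in a fixed order: (1) duplicate removal — the same charged mass
annotated twice, either because a suspect sits in two overlapping
acquisition windows or because a salt and its free acid collapse to one
anion, keeps the annotation with the higher S/N; (2) isotope-score
threshold — scored (L-4) candidates below the minimum similarity are
dropped, unscored (L-5) candidates pass since they carry no score;
(3) pKa-based exclusion — only candidates with an acidic ionization site
are plausible in negative ESI, non-ionizable and electropositive
(basic-only) suspects are excluded with the reason recorded;
(4) fragment exclusion — heteroatom-free compositions
((O+S+P+N)/C = 0) likely stem from in-source fragments of PFAS and are
removed; (5) composite ranking — |ppm error|, QC level and acidic pKa
are each normalized to [0, 1] (0 best) and averaged with equal weight.

Every stage records in/out counts in a funnel report whose arithmetic
(kept + removed = in) is enforced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from pfas_screen.matching import CandidateMatch
from pfas_screen.scoring import L4, L5, IsotopeScoreResult
from pfas_screen.suspects import ACIDIC, ELECTROPOSITIVE, NON_IONIZABLE, SuspectEntry

__all__ = [
    "Candidate",
    "RankedCandidate",
    "FunnelReport",
    "attach_suspects",
    "dedup",
    "similarity_threshold",
    "pka_exclusion",
    "fragment_exclusion",
    "composite_rank",
    "funnel_report",
    "run_filters",
    "OfflineFormulaHook",
    "ranked_to_frame",
]


@dataclass
class Candidate:
    """One annotation carried through the filter funnel."""

    suspect: SuspectEntry
    match: CandidateMatch
    result: IsotopeScoreResult

    @property
    def charged_mass(self) -> float:
        return self.suspect.charged_mass

    @property
    def snr(self) -> float:
        return self.match.peak.snr

    @property
    def score(self) -> float | None:
        return self.result.score

    @property
    def level(self) -> str:
        return self.result.level


@dataclass
class RankedCandidate:
    """A surviving candidate with its normalized ranking variables."""

    candidate: Candidate
    norm_mass_acc: float
    norm_qc: float
    norm_pka: float
    composite: float
    rank: int = 0


class FunnelReport:
    """Stage-by-stage candidate bookkeeping with enforced conservation."""

    def __init__(self):
        self.stages: list[dict] = []

    def add(self, name: str, n_in: int, n_out: int, reason: str = "") -> None:
        self.stages.append(
            {
                "stage": name,
                "n_in": n_in,
                "n_removed": n_in - n_out,
                "n_out": n_out,
                "reason": reason,
            }
        )

    def check(self) -> None:
        """Raise if any stage loses or invents candidates."""
        prev_out: int | None = None
        for s in self.stages:
            if s["n_in"] - s["n_removed"] != s["n_out"] or s["n_removed"] < 0:
                raise RuntimeError(f"funnel stage inconsistent: {s}")
            if prev_out is not None and s["n_in"] != prev_out:
                raise RuntimeError(
                    f"funnel discontinuity: stage {s['stage']!r} starts with "
                    f"{s['n_in']} but previous stage left {prev_out}"
                )
            prev_out = s["n_out"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages,
            columns=["stage", "n_in", "n_removed", "n_out", "reason"],
        )

    def __str__(self) -> str:
        lines = [
            f"{s['stage']}: {s['n_in']} -> {s['n_out']} "
            f"(-{s['n_removed']}{': ' + s['reason'] if s['reason'] else ''})"
            for s in self.stages
        ]
        return "\n".join(lines)


def funnel_report(
    stage_counts: Sequence[tuple[str, int, int]] | Sequence[tuple[str, int, int, str]],
) -> FunnelReport:
    """Build and validate a funnel report from (stage, n_in, n_out) tuples."""
    report = FunnelReport()
    for row in stage_counts:
        report.add(*row)
    report.check()
    return report


def attach_suspects(
    results: Sequence[IsotopeScoreResult],
    suspects_by_id: dict[str, SuspectEntry],
) -> list[Candidate]:
    return [
        Candidate(
            suspect=suspects_by_id[r.candidate.suspect_id],
            match=r.candidate,
            result=r,
        )
        for r in results
    ]


def dedup(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Remove duplicate annotations of one charged mass, keeping max S/N.

    Groups by the suspect's charged mass, which is bit-identical for a
    salt and its free acid (both are curated through the same
    re-protonated parent) and for one suspect matched in two overlapping
    windows.  Ties on S/N keep the first occurrence (stable).
    """
    best: dict[float, Candidate] = {}
    order: list[float] = []
    for c in candidates:
        key = c.charged_mass
        if key not in best:
            best[key] = c
            order.append(key)
        elif c.snr > best[key].snr:
            best[key] = c
    return [best[k] for k in order]


def similarity_threshold(
    candidates: Sequence[Candidate], min_score: float = 75.0
) -> list[Candidate]:
    """Drop scored (L-4) candidates below ``min_score``; L-5 pass through."""
    return [
        c
        for c in candidates
        if c.level == L5 or (c.score is not None and c.score >= min_score)
    ]


def pka_exclusion(
    candidates: Sequence[Candidate],
) -> tuple[list[Candidate], list[Candidate], list[Candidate]]:
    """Partition by negative-ESI plausibility.

    Returns ``(kept, excluded_non_ionizable, excluded_electropositive)``:
    only acidic candidates are kept, the exclusions are split by reason
    for the funnel report.
    """
    kept, non_ion, electro = [], [], []
    for c in candidates:
        cls = c.suspect.ionizability
        if cls == ACIDIC:
            kept.append(c)
        elif cls == ELECTROPOSITIVE:
            electro.append(c)
        else:
            non_ion.append(c)
    return kept, non_ion, electro


def fragment_exclusion(candidates: Sequence[Candidate]) -> list[Candidate]:
    """Remove heteroatom-free candidates ((O+S+P+N)/C = 0).

    Such compositions contain no heteroatom besides fluorine and most
    likely originate from in-source fragments of PFAS rather than intact
    molecules.
    """
    out = []
    for c in candidates:
        hetero_c = c.suspect.descriptors.hetero_c
        if not math.isnan(hetero_c) and hetero_c == 0:
            continue
        out.append(c)
    return out


def _minmax(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi == lo:  # degenerate: everything is equally good
        return [0.0 for _ in values]
    return [(v - lo) / (hi - lo) for v in values]


def composite_rank(candidates: Sequence[Candidate]) -> list[RankedCandidate]:
    """Rank candidates by the mean of three normalized variables.

    |ppm error| and acidic pKa are min-max normalized over the candidate
    set (lowest -> 0, highest -> 1); the discrete QC level maps linearly
    1 -> 0 ... 5 -> 1.  The composite is their unweighted mean; lower is
    better.  Sorting is ascending by composite with a stable tie-break on
    charged mass.
    """
    if not candidates:
        return []
    abs_ppm = [abs(c.match.ppm_error) for c in candidates]
    pkas = []
    for c in candidates:
        if c.suspect.pka_acidic is None:
            warnings.warn(
                f"candidate {c.suspect.id} lacks an acidic pKa; "
                "assigned worst normalized value 1",
                stacklevel=2,
            )
            pkas.append(None)
        else:
            pkas.append(c.suspect.pka_acidic)
    present = [p for p in pkas if p is not None]
    norm_pka_present = _minmax(present) if present else []
    it = iter(norm_pka_present)
    norm_pka = [1.0 if p is None else next(it) for p in pkas]
    norm_ppm = _minmax(abs_ppm)
    ranked = []
    for c, nppm, npka in zip(candidates, norm_ppm, norm_pka):
        if c.suspect.qc_level is None:
            warnings.warn(
                f"candidate {c.suspect.id} lacks a QC level; "
                "assigned worst normalized value 1",
                stacklevel=2,
            )
            nqc = 1.0
        else:
            nqc = (c.suspect.qc_level - 1) / 4.0
        composite = (nppm + nqc + npka) / 3.0
        ranked.append(
            RankedCandidate(
                candidate=c,
                norm_mass_acc=nppm,
                norm_qc=nqc,
                norm_pka=npka,
                composite=composite,
            )
        )
    ranked.sort(key=lambda r: (r.composite, r.candidate.charged_mass))
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


class OfflineFormulaHook:
    """Interface for external formula lookup by accurate m/z.

    The original workflow offers a live PubChem query for candidates that
    cannot be validated by isotopologues; this package keeps the core
    network-free and exposes the lookup as a replaceable hook.  The stub
    returns no formulas.  Subclass (or duck-type) with
    ``query(mz, tol_ppm) -> list[str]`` backed by a local snapshot to
    enable cross-validation.
    """

    def query(self, mz: float, tol_ppm: float = 1.5) -> list[str]:
        return []


def run_filters(
    results: Sequence[IsotopeScoreResult],
    suspects_by_id: dict[str, SuspectEntry],
    min_score: float = 75.0,
    apply_fragment_exclusion: bool = True,
) -> tuple[list[RankedCandidate], FunnelReport]:
    """Run the full funnel: dedup -> score -> pKa -> fragment -> rank."""
    candidates = attach_suspects(results, suspects_by_id)
    report = FunnelReport()

    after_dedup = dedup(candidates)
    report.add("dedup", len(candidates), len(after_dedup), "duplicate charged mass")

    after_score = similarity_threshold(after_dedup, min_score)
    report.add(
        "similarity_threshold",
        len(after_dedup),
        len(after_score),
        f"isotope score < {min_score:g}",
    )

    kept, non_ion, electro = pka_exclusion(after_score)
    report.add(
        "pka_non_ionizable",
        len(after_score),
        len(after_score) - len(non_ion),
        "no ionizable site",
    )
    report.add(
        "pka_electropositive",
        len(after_score) - len(non_ion),
        len(kept),
        "positive-mode only",
    )

    if apply_fragment_exclusion:
        after_frag = fragment_exclusion(kept)
        report.add(
            "fragment_exclusion",
            len(kept),
            len(after_frag),
            "(O+S+P+N)/C = 0",
        )
    else:
        after_frag = kept

    ranked = composite_rank(after_frag)
    report.check()
    return ranked, report


def ranked_to_frame(ranked: Sequence[RankedCandidate]) -> pd.DataFrame:
    """Final candidate table, one row per ranked annotation."""
    rows = []
    for r in ranked:
        c = r.candidate
        rows.append(
            {
                "rank": r.rank,
                "composite": r.composite,
                "suspect_id": c.suspect.id,
                "formula": c.suspect.neutral_formula.hill(),
                "measured_mz": c.match.peak.mz,
                "theoretical_mz": c.match.theoretical_mz,
                "ppm_error": c.match.ppm_error,
                "intensity": c.match.peak.intensity,
                "snr": c.snr,
                "score": c.score,
                "level": c.level,
                "qc_level": c.suspect.qc_level,
                "pka_acidic": c.suspect.pka_acidic,
                "norm_mass_acc": r.norm_mass_acc,
                "norm_qc": r.norm_qc,
                "norm_pka": r.norm_pka,
                "window": c.match.window,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "composite",
            "suspect_id",
            "formula",
            "measured_mz",
            "theoretical_mz",
            "ppm_error",
            "intensity",
            "snr",
            "score",
            "level",
            "qc_level",
            "pka_acidic",
            "norm_mass_acc",
            "norm_qc",
            "norm_pka",
            "window",
        ],
    )
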