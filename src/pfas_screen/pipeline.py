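"""End-to-end screening pipeline and plot-ready table export.

Wires the stages in their fixed order: window trimming and stitching,
optional blank filtering, suspect matching, isotopologue scoring, and the
candidate funnel (dedup, score threshold, pKa exclusion, fragment
exclusion, composite ranking).  Also exports the visualization tables —
Kendrick mass defect, mass defect distribution and elemental ratios —
for the final candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from pfas_screen.chem import kendrick
from pfas_screen.matching import match_suspects, matches_to_frame
from pfas_screen.ranking import (
    FunnelReport,
    RankedCandidate,
    ranked_to_frame,
    run_filters,
)
from pfas_screen.scoring import score_all
from pfas_screen.spectra import (
    MergedPeakList,
    Spectrum,
    blank_filter,
    merge_windows,
    trim_to_window,
)
from pfas_screen.suspects import SuspectList

__all__ = ["ScreenParams", "ScreenResult", "screen", "export_plot_tables", "render_plots"]


@dataclass
class ScreenParams:
    """Screening parameters; defaults are the workflow's standard values."""

    tol_ppm: float = 1.5
    k: int = 10
    min_score: float = 75.0
    overlap: float = 5.0
    blank_ppm_tol: float | None = None  # defaults to tol_ppm
    blank_ratio_min: float = 10.0
    apply_blank_filter: bool = True
    apply_fragment_exclusion: bool = True

    def __post_init__(self):
        if self.tol_ppm <= 0 or self.min_score < 0 or self.overlap < 0:
            raise ValueError("invalid screening parameters")
        if self.blank_ppm_tol is None:
            self.blank_ppm_tol = self.tol_ppm


@dataclass
class ScreenResult:
    """Everything the screening run produced, ready for CSV export."""

    merged: MergedPeakList
    n_blank_flagged: int
    matches: pd.DataFrame
    ranked: list[RankedCandidate]
    final: pd.DataFrame
    funnel: FunnelReport

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.matches.to_csv(out / "candidates.csv", index=False)
        self.final.to_csv(out / "final_candidates.csv", index=False)
        self.funnel.to_frame().to_csv(out / "funnel.csv", index=False)
        for name, table in export_plot_tables(self.ranked).items():
            table.to_csv(out / f"plot_{name}.csv", index=False)


def screen(
    spectra: Sequence[Spectrum],
    suspects: SuspectList,
    blank: Spectrum | Sequence[Spectrum] | None = None,
    params: ScreenParams | None = None,
) -> ScreenResult:
    """Run the full screening pipeline on windowed spectra."""
    params = params or ScreenParams()
    trimmed = [trim_to_window(s, params.overlap) for s in spectra]
    merged = merge_windows(trimmed)
    n_flagged = 0
    if blank is not None and params.apply_blank_filter:
        blank_list = [blank] if isinstance(blank, Spectrum) else list(blank)
        blank_merged = merge_windows(blank_list)
        merged, flagged = blank_filter(
            merged,
            blank_merged,
            ppm_tol=params.blank_ppm_tol,
            ratio_min=params.blank_ratio_min,
        )
        n_flagged = len(flagged)

    suspects_by_id = {e.id: e for e in suspects.entries}
    matches = match_suspects(
        merged, suspects.entries, k=params.k, tol_ppm=params.tol_ppm
    )
    scores = score_all(matches, suspects_by_id, merged, tol_ppm=params.tol_ppm)
    ranked, funnel = run_filters(
        scores,
        suspects_by_id,
        min_score=params.min_score,
        apply_fragment_exclusion=params.apply_fragment_exclusion,
    )
    return ScreenResult(
        merged=merged,
        n_blank_flagged=n_flagged,
        matches=matches_to_frame(matches),
        ranked=ranked,
        final=ranked_to_frame(ranked),
        funnel=funnel,
    )


def export_plot_tables(ranked: Sequence[RankedCandidate]) -> dict[str, pd.DataFrame]:
    """Plot-ready tables for the final candidate list.

    ``kendrick``: CF2-based Kendrick mass and mass defect per candidate;
    ``mass_defect``: measured m/z vs. signed mass defect;
    ``elemental_ratios``: the (H+Halogens)/C vs. (O+S+P+N)/C plane plus
    the classic F/C, H/C, O/C ratios and DBE.
    """
    kmd_rows, md_rows, ratio_rows = [], [], []
    for r in ranked:
        c = r.candidate
        mz = c.match.peak.mz
        km, kmd = kendrick(mz)
        desc = c.suspect.descriptors
        base = {"suspect_id": c.suspect.id, "measured_mz": mz, "rank": r.rank}
        kmd_rows.append({**base, "kendrick_mass": km, "kmd": kmd})
        md_rows.append({**base, "mass_defect": desc.mass_defect})
        ratio_rows.append(
            {
                **base,
                "(H+Hal)/C": desc.h_hal_c,
                "(O+S+P+N)/C": desc.hetero_c,
                "F/C": desc.f_c,
                "H/C": desc.h_c,
                "O/C": desc.o_c,
                "DBE": desc.dbe,
            }
        )
    cols_kmd = ["suspect_id", "measured_mz", "rank", "kendrick_mass", "kmd"]
    cols_md = ["suspect_id", "measured_mz", "rank", "mass_defect"]
    cols_ratio = [
        "suspect_id", "measured_mz", "rank",
        "(H+Hal)/C", "(O+S+P+N)/C", "F/C", "H/C", "O/C", "DBE",
    ]
    return {
        "kendrick": pd.DataFrame(kmd_rows, columns=cols_kmd),
        "mass_defect": pd.DataFrame(md_rows, columns=cols_md),
        "elemental_ratios": pd.DataFrame(ratio_rows, columns=cols_ratio),
    }


def render_plots(
    ranked: Sequence[RankedCandidate], out_dir: str | Path
) -> list[Path]:
    """Render the three standard plots as PNG files (optional step)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tables = export_plot_tables(ranked)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots()
    t = tables["kendrick"]
    ax.scatter(t["kendrick_mass"], t["kmd"], s=12)
    ax.set_xlabel("Kendrick mass (CF2)")
    ax.set_ylabel("Kendrick mass defect")
    fig.savefig(out / "kendrick.png", dpi=120)
    plt.close(fig)
    written.append(out / "kendrick.png")

    fig, ax = plt.subplots()
    t = tables["mass_defect"]
    ax.scatter(t["measured_mz"], t["mass_defect"], s=12)
    ax.set_xlabel("m/z")
    ax.set_ylabel("mass defect")
    fig.savefig(out / "mass_defect.png", dpi=120)
    plt.close(fig)
    written.append(out / "mass_defect.png")

    fig, ax = plt.subplots()
    t = tables["elemental_ratios"]
    ax.scatter(t["(O+S+P+N)/C"], t["(H+Hal)/C"], s=12)
    ax.set_xlabel("(O+S+P+N)/C")
    ax.set_ylabel("(H+Halogens)/C")
    fig.savefig(out / "elemental_ratios.png", dpi=120)
    plt.close(fig)
    written.append(out / "elemental_ratios.png")
    return written
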