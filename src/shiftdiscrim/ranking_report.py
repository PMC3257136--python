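"""Rank candidate structures and render the discrimination report.

Candidates are compared block by block, a block being one (nucleus, method)
combination.  The default criterion orders by cross-validated Q^2
(descending), breaking ties by lower MAE and then lower s_PRESS.  The overall
verdict is the candidate winning the most blocks; on a tie, carbon blocks
outrank proton blocks (the discriminating residues sit on carbon skeleton
positions adjacent to the heteroatom).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .shift_data import Nucleus, ValidationError
from .discrimination_stats import CandidateScore

__all__ = ["DiscriminationReport", "rank_candidates", "render_report", "scatter_data"]

Criterion = Literal["q2", "mae", "r2", "composite"]

#: Report column order (one row per candidate x nucleus x method).
REPORT_COLUMNS = [
    "candidate", "nucleus", "method",
    "a", "b", "R2", "MAE", "CMAE", "s", "PRESS", "s_PRESS", "F", "Q2",
]


@dataclass(frozen=True)
class DiscriminationReport:
    scores: tuple[CandidateScore, ...]
    rankings: dict[tuple[Nucleus, str], tuple[str, ...]]
    block_winners: dict[tuple[Nucleus, str], str]
    verdict: str
    criterion: Criterion
    ties: tuple[str, ...] = ()   # human-readable notes on ties encountered


def _sort_key(score: CandidateScore, criterion: Criterion):
    if criterion == "q2":
        return (-score.cv.q2, score.mae, score.cv.s_press, score.candidate)
    if criterion == "mae":
        return (score.mae, -score.cv.q2, score.cv.s_press, score.candidate)
    if criterion == "r2":
        return (-score.pred_fit.r2, score.mae, score.cv.s_press, score.candidate)
    raise ValueError(f"unknown criterion: {criterion!r}")


def _rank_block(scores: list[CandidateScore], criterion: Criterion) -> list[CandidateScore]:
    if criterion == "composite":
        # mean rank over the three simple criteria, lower is better
        order: dict[str, float] = {s.candidate: 0.0 for s in scores}
        for sub in ("q2", "mae", "r2"):
            for rank, sc in enumerate(sorted(scores, key=lambda s: _sort_key(s, sub))):
                order[sc.candidate] += rank / 3.0
        return sorted(scores, key=lambda s: (order[s.candidate], _sort_key(s, "q2")))
    return sorted(scores, key=lambda s: _sort_key(s, criterion))


def rank_candidates(
    scores: Iterable[CandidateScore], criterion: Criterion = "q2"
) -> DiscriminationReport:
    """Rank candidates within every (nucleus, method) block and decide an
    overall verdict by majority of block wins (carbon breaks ties)."""
    scores = tuple(scores)
    if not scores:
        raise ValidationError("no candidate scores supplied")

    # Candidates are only comparable within a compound (same measured
    # spectrum); compounds carrying a single candidate — reference compounds
    # run through the same pipeline — are reported but not ranked.
    by_compound: dict[str, list[CandidateScore]] = {}
    for sc in scores:
        by_compound.setdefault(sc.compound, []).append(sc)
    rankable = {
        comp: grp for comp, grp in by_compound.items()
        if len({s.candidate for s in grp}) >= 2
    }
    if not rankable:
        raise ValidationError("no compound has two candidates to compare")

    blocks: dict[tuple[Nucleus, str], list[CandidateScore]] = {}
    for grp in rankable.values():
        for sc in grp:
            key = (sc.nucleus, sc.method)
            if any(s.compound != sc.compound for s in blocks.get(key, [])):
                raise ValidationError(
                    f"block ({sc.nucleus.value}, {sc.method}) mixes compounds; "
                    "rank each compound in a separate run"
                )
            blocks.setdefault(key, []).append(sc)

    # every ranked candidate must appear in every block of its compound
    multi = {s.candidate for blk in blocks.values() for s in blk}
    missing = [
        (cand, nuc.value, meth)
        for (nuc, meth), blk in blocks.items()
        for cand in multi
        if not any(s.candidate == cand for s in blk)
    ]
    if missing:
        raise ValidationError(f"candidates missing from blocks: {missing}")

    rankings: dict[tuple[Nucleus, str], tuple[str, ...]] = {}
    winners: dict[tuple[Nucleus, str], str] = {}
    ties: list[str] = []
    for key, blk in blocks.items():
        ordered = _rank_block(blk, criterion)
        rankings[key] = tuple(s.candidate for s in ordered)
        winners[key] = ordered[0].candidate
        if len(ordered) > 1 and np.isclose(ordered[0].cv.q2, ordered[1].cv.q2) \
                and np.isclose(ordered[0].mae, ordered[1].mae):
            ties.append(
                f"tie in block ({key[0].value}, {key[1]}) broken by label order: "
                f"{ordered[0].candidate} before {ordered[1].candidate}"
            )

    wins: dict[str, int] = {}
    c13_wins: dict[str, int] = {}
    for (nuc, _), cand in winners.items():
        wins[cand] = wins.get(cand, 0) + 1
        if nuc is Nucleus.C13:
            c13_wins[cand] = c13_wins.get(cand, 0) + 1
    verdict = sorted(wins, key=lambda c: (-wins[c], -c13_wins.get(c, 0), c))[0]
    top = [c for c in wins if wins[c] == wins[verdict]]
    if len(top) > 1:
        ties.append(f"overall tie between {sorted(top)}; carbon blocks decided")
    return DiscriminationReport(
        scores=scores, rankings=rankings, block_winners=winners,
        verdict=verdict, criterion=criterion, ties=tuple(ties),
    )


def _rounded_row(sc: CandidateScore) -> dict:
    """One report row, rounded as in the reference tables (a, b, MAE, CMAE,
    R2, F to 2 dp; s to 4 dp; PRESS to 6 significant figures; Q2 in %)."""
    press = float(f"{sc.cv.press:.6g}")
    return {
        "candidate": sc.candidate,
        "nucleus": sc.nucleus.value,
        "method": sc.method,
        "a": round(sc.fit.a, 2),
        "b": round(sc.fit.b, 2),
        "R2": round(sc.pred_fit.r2, 2),
        "MAE": round(sc.mae, 2),
        "CMAE": round(sc.cmae, 2),
        "s": round(sc.pred_fit.s, 4),
        "PRESS": press,
        "s_PRESS": round(sc.cv.s_press, 2),
        "F": round(sc.pred_fit.f_stat, 2),
        "Q2": round(100.0 * sc.cv.q2, 2),
    }


def scores_frame(scores: Iterable[CandidateScore]) -> pd.DataFrame:
    """Statistic rows only (no ranking) — e.g. for a single-candidate run."""
    return pd.DataFrame([_rounded_row(s) for s in scores], columns=REPORT_COLUMNS)


def report_frame(report: DiscriminationReport) -> pd.DataFrame:
    return scores_frame(report.scores)


def render_report(
    report: DiscriminationReport,
    format: Literal["text", "csv", "json"] = "text",
    include_residuals: bool = False,
) -> str:
    """Serialise a report; a pure function of its input (byte-identical
    across runs on the same data)."""
    frame = report_frame(report)
    if format == "csv":
        return frame.to_csv(index=False)
    if format == "json":
        payload = {
            "criterion": report.criterion,
            "verdict": report.verdict,
            "block_winners": {
                f"{nuc.value}|{meth}": cand
                for (nuc, meth), cand in report.block_winners.items()
            },
            "rankings": {
                f"{nuc.value}|{meth}": list(order)
                for (nuc, meth), order in report.rankings.items()
            },
            "ties": list(report.ties),
            "rows": frame.to_dict(orient="records"),
        }
        if include_residuals:
            payload["residuals"] = {
                f"{s.candidate}|{s.nucleus.value}|{s.method}": list(s.rs)
                for s in report.scores
            }
        return json.dumps(payload, ensure_ascii=False, indent=2, sort_keys=True)
    if format == "text":
        buf = io.StringIO()
        buf.write(frame.to_string(index=False))
        buf.write("\n\nBlock winners:\n")
        for (nuc, meth), cand in report.block_winners.items():
            buf.write(f"  {nuc.value:4s} {meth}: {cand}\n")
        for note in report.ties:
            buf.write(f"  note: {note}\n")
        buf.write(f"\nVerdict ({report.criterion}): {report.verdict}\n")
        if include_residuals:
            buf.write("\nPer-position residues (ppm):\n")
            for s in report.scores:
                rs = ", ".join(f"{v:.2f}" for v in s.rs)
                buf.write(f"  {s.candidate} {s.nucleus.value} {s.method}: {rs}\n")
        return buf.getvalue()
    raise ValueError(f"unknown format: {format!r}")


def scatter_data(scores: Iterable[CandidateScore], tables) -> pd.DataFrame:
    """Correlation-plot data: (delta_exp, delta_calc, fitted) per candidate,
    for external plotting.  ``tables`` maps (candidate, nucleus, method) to
    the originating ShiftTable."""
    rows = []
    for sc in scores:
        table = tables[(sc.candidate, sc.nucleus, sc.method)]
        fitted = sc.fit.predict(np.asarray(table.delta_exp))
        for pos, e, c, f in zip(table.positions, table.delta_exp, table.delta_calc, fitted):
            rows.append({
                "candidate": sc.candidate, "nucleus": sc.nucleus.value,
                "method": sc.method, "position": pos,
                "delta_exp": e, "delta_calc": c, "fitted": float(f),
            })
    return pd.DataFrame(rows)
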