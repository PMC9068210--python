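"""Zahnreihen-graph plotting: tooth position vs maturity stage."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from zahnreihen.analysis import ZSpacingReport
from zahnreihen.model import MATURITY_LADDER

__all__ = ["plot_zahnreihen"]

_STAGE_BY_SCORE = {v: k for k, v in MATURITY_LADDER.items()}


def plot_zahnreihen(report: ZSpacingReport, path: Union[str, Path]) -> None:
    """Plot a quadrant's Zahnreihen graph to ``path`` (format by extension).

    Functional teeth are drawn as filled triangles, replacement teeth as
    grey circles, and each Zahnreihe as a connecting polyline; exception
    points stand alone.  The y-axis is the unified 7-step maturity
    ladder.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    all_points = [p for run in report.zahnreihen for p in run.points] + list(
        report.exceptions
    )
    funct = [p for p in all_points if p.is_functional]
    repl = [p for p in all_points if not p.is_functional]
    if funct:
        ax.scatter(
            [p.position for p in funct],
            [p.score for p in funct],
            marker="^",
            color="black",
            zorder=3,
            label="functional tooth",
        )
    if repl:
        ax.scatter(
            [p.position for p in repl],
            [p.score for p in repl],
            marker="o",
            color="0.6",
            zorder=3,
            label="replacement tooth",
        )
    for run in report.zahnreihen:
        ax.plot(run.positions, run.scores, color="black", linewidth=1, zorder=2)
    for p in all_points:
        if p.label:
            ax.annotate(
                p.label, (p.position, p.score), textcoords="offset points",
                xytext=(0, 6), fontsize=7, ha="center",
            )
    ax.set_xlabel("tooth position (rostral → caudal)")
    ax.set_ylabel("tooth replacement stage")
    ax.set_yticks(sorted(_STAGE_BY_SCORE))
    ax.set_yticklabels([_STAGE_BY_SCORE[s] for s in sorted(_STAGE_BY_SCORE)])
    ax.set_ylim(0.5, 7.5)
    if all_points:
        ax.set_xticks(sorted({p.position for p in all_points}))
    title = " ".join(
        part for part in (report.specimen_id, report.element, report.side) if part
    )
    if title:
        ax.set_title(title)
    if funct or repl:
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
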