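"""Per-cluster end-of-life quality tables.

Summarizes, for each pathway cluster and for the aggregate with/without
palliative-care groups: cluster share, per-service utilization and median
initiation day (among users of that service), the five 30-day end-of-life
indicators, and the place-of-death distribution.  Lower utilization of
aggressive care near death and fewer in-hospital deaths are read as higher
end-of-life care quality.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._rounding import pct, round_half_up
from .cohort import CohortMember
from .datasets import EOL_EVENTS, PALLIATIVE_SERVICES, PLACES_OF_DEATH

__all__ = ["service_utilization", "cluster_quality_table", "plot_cluster_timelines"]


def service_utilization(cohort_with_pc: list[CohortMember]) -> pd.DataFrame:
    """Count and percentage of palliative-care users per service type.

    Denominator = number of members with any palliative care.  Empty input
    yields an empty table.
    """
    if not cohort_with_pc:
        return pd.DataFrame(columns=["service", "count", "pct"])
    for m in cohort_with_pc:
        if not m.has_palliative_care:
            raise ValueError(f"{m.individual_id} has no palliative-care service")
    n = len(cohort_with_pc)
    rows = [
        {
            "service": s,
            "count": (cnt := sum(s in m.pc_initiation for m in cohort_with_pc)),
            "pct": pct(cnt, n),
        }
        for s in PALLIATIVE_SERVICES
    ]
    return pd.DataFrame(rows)


def _quality_row(members: list[CohortMember], share_denominator: int | None) -> dict:
    n = len(members)
    row: dict[str, float] = {"n": n}
    row["share_pct"] = pct(n, share_denominator) if share_denominator else float("nan")
    for s in PALLIATIVE_SERVICES:
        users = [m.pc_initiation[s] for m in members if s in m.pc_initiation]
        row[f"{s.lower()}_pct"] = pct(len(users), n)
        row[f"{s.lower()}_median_day"] = (
            round_half_up(float(np.median(users)), 1) if users else float("nan")
        )
    for event in EOL_EVENTS:
        key = event.lower()
        row[f"{key}_30d_pct"] = pct(
            sum(m.eol_flags.get(key, False) for m in members), n
        )
    for place in PLACES_OF_DEATH:
        row[f"pod_{place}_pct"] = pct(
            sum(m.place_of_death == place for m in members), n
        )
    return row


def cluster_quality_table(
    cohort: list[CohortMember], labels: dict[str, int]
) -> pd.DataFrame:
    """Quality table: one row per cluster plus with-PC / without-PC rows.

    ``labels`` must cover exactly the members with a non-empty pathway.
    Medians use only users of the respective service within the row's group;
    cluster shares are percentages of all members with palliative care.
    """
    with_pc = [m for m in cohort if m.has_palliative_care]
    without_pc = [m for m in cohort if not m.has_palliative_care]
    expected = {m.individual_id for m in with_pc}
    got = set(labels)
    if got != expected:
        extra, missing = sorted(got - expected), sorted(expected - got)
        raise ValueError(
            f"labels must cover exactly the members with palliative care "
            f"(unknown or pathway-less: {extra[:5]}, unlabeled: {missing[:5]})"
        )

    n_pc = len(with_pc)
    rows = {}
    for cluster_id in sorted(set(labels.values())):
        members = [m for m in with_pc if labels[m.individual_id] == cluster_id]
        rows[str(cluster_id)] = _quality_row(members, n_pc)
    rows["with_pc"] = _quality_row(with_pc, None)
    rows["without_pc"] = _quality_row(without_pc, None)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "cluster"
    return table


def write_quality_report(table: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "table2.csv")
    (out / "table2.md").write_text(_markdown_table(table))


def _markdown_table(table: pd.DataFrame) -> str:
    cols = [table.index.name or ""] + list(table.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for idx, row in table.iterrows():
        cells = [str(idx)] + [
            "" if pd.isna(v) else (f"{v:.1f}" if isinstance(v, float) else str(v))
            for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def plot_cluster_timelines(
    cohort: list[CohortMember],
    labels: dict[str, int],
    path: str | Path | None = None,
):
    """Death-anchored initiation timelines, one panel per cluster.

    Each marker is one service initiation of one individual, plotted at its
    day before death (x axis reversed so death sits at the right edge).
    Requires matplotlib; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = sorted(set(labels.values()))
    by_id = {m.individual_id: m for m in cohort}
    fig, axes = plt.subplots(
        len(clusters), 1, figsize=(8, 1.6 * len(clusters)), sharex=True, squeeze=False
    )
    colors = dict(zip(PALLIATIVE_SERVICES, ["#2a9d8f", "#e76f51", "#264653", "#e9c46a"]))
    for ax, cluster_id in zip(axes.ravel(), clusters):
        members = [by_id[i] for i, c in labels.items() if c == cluster_id]
        for y, m in enumerate(members):
            for s, day in m.pc_initiation.items():
                ax.plot(day, y, "o", ms=3, color=colors[s])
        ax.set_ylabel(f"cluster {cluster_id}\n(n={len(members)})", fontsize=8)
        ax.set_yticks([])
    axes.ravel()[-1].set_xlabel("days before death")
    axes.ravel()[-1].set_xlim(370, -5)
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=c, label=s)
        for s, c in colors.items()
    ]
    fig.legend(handles=handles, loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
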