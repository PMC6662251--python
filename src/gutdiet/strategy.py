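"""The modified Costello (Amundsen) feeding-strategy diagram.

Each prey of a group is plotted as a point (x = frequency of occurrence
F_i, y = prey-specific abundance P_i).  The diagram reads qualitatively:

* lower-left -> upper-right diagonal: prey importance (dominant prey sit
  in the top-right corner, rare prey at the lower-left end);
* vertical axis: feeding strategy (prey in the upper half indicate
  specialization, all prey in the lower half a generalized strategy);
* upper-left -> lower-right diagonal: phenotype contribution to niche
  width — upper-left points mean a high between-phenotype component
  (BPC: different individuals specialize on different prey), lower-right
  a high within-phenotype component (WPC: most individuals take many
  prey).

The source method gives no numeric quadrant boundaries; the defaults
here are the plot midpoints (50, 50), configurable.  Points exactly on a
threshold line are assigned to the upper/dominant side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, GutDietError
from .indices import PreyImportanceTable, round_half_up


@dataclass(frozen=True)
class StrategyPoint:
    """One prey of one group in diagram coordinates (percent)."""

    prey: str
    frequency: float  # x = F_i
    prey_specific_abundance: float  # y = P_i


@dataclass(frozen=True)
class PreyLabels:
    importance: str  # dominant | rare | intermediate
    tendency: str  # specialization | generalization
    phenotype: str  # bpc | wpc | mixed
    score: float  # position along the importance diagonal, (x + y) / 2


@dataclass(frozen=True)
class StrategyReport:
    """Classified diagram for one (species, season) group."""

    species: str
    season: str
    points: tuple[StrategyPoint, ...]
    labels: dict[str, PreyLabels]
    group_label: str  # specialized | generalized (| mixed, reserved)
    x_threshold: float = 50.0
    y_threshold: float = 50.0

    @property
    def group_key(self) -> tuple[str, str]:
        return (self.species, self.season)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            lab = self.labels[pt.prey]
            rows.append(
                {
                    "prey_category": pt.prey,
                    "frequency_of_occurrence": pt.frequency,
                    "prey_specific_abundance": pt.prey_specific_abundance,
                    "importance": lab.importance,
                    "tendency": lab.tendency,
                    "phenotype_component": lab.phenotype,
                    "importance_score": lab.score,
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["importance_score", "prey_category"], ascending=[False, True]
        ).reset_index(drop=True)


def costello_points(importance: PreyImportanceTable) -> list[StrategyPoint]:
    """Diagram coordinates (F_i, P_i) for every prey of a group."""
    if importance.frame.empty:
        raise GutDietError(f"group {importance.group_key}: empty importance table")
    return [
        StrategyPoint(prey=prey, frequency=float(row["F"]), prey_specific_abundance=float(row["P"]))
        for prey, row in importance.frame.iterrows()
    ]


def classify_points(
    points: list[StrategyPoint],
    species: str = "",
    season: str = "",
    x_threshold: float = 50.0,
    y_threshold: float = 50.0,
) -> StrategyReport:
    """Label each prey by diagram quadrant and the group by strategy.

    With upper = (P_i >= y_threshold) and right = (F_i >= x_threshold):
    dominant prey are upper-right, rare prey lower-left, the rest
    intermediate; upper points read as specialization and carry a BPC
    flag when they are also left of the x threshold; lower-right points
    carry a WPC flag.  The group is "specialized" if any prey lies in
    the upper half, "generalized" if all prey lie below it.
    """
    for name, thr in (("x_threshold", x_threshold), ("y_threshold", y_threshold)):
        if not (0.0 < thr < 100.0):
            raise ConfigurationError(f"{name} must be in (0, 100), got {thr}")
    if not points:
        raise GutDietError("no points to classify")
    labels: dict[str, PreyLabels] = {}
    any_upper = False
    for pt in points:
        upper = pt.prey_specific_abundance >= y_threshold
        right = pt.frequency >= x_threshold
        any_upper = any_upper or upper
        if upper and right:
            importance = "dominant"
        elif not upper and not right:
            importance = "rare"
        else:
            importance = "intermediate"
        tendency = "specialization" if upper else "generalization"
        if upper and not right:
            phenotype = "bpc"
        elif right and not upper:
            phenotype = "wpc"
        else:
            phenotype = "mixed"
        labels[pt.prey] = PreyLabels(
            importance=importance,
            tendency=tendency,
            phenotype=phenotype,
            score=(pt.frequency + pt.prey_specific_abundance) / 2.0,
        )
    group_label = "specialized" if any_upper else "generalized"
    return StrategyReport(
        species=species,
        season=season,
        points=tuple(points),
        labels=labels,
        group_label=group_label,
        x_threshold=x_threshold,
        y_threshold=y_threshold,
    )


def export_diagram(
    reports: StrategyReport | list[StrategyReport],
    figure_path: str | Path | None,
    coords_path: str | Path,
    digits: int = 2,
) -> pd.DataFrame:
    """Write the coordinates table and (optionally) render the diagram.

    The coordinates TSV carries one row per (group, prey) with both axes
    rounded half-up to ``digits`` — byte-identical across runs for the
    same report.  When ``figure_path`` is given a scatter panel per
    group is rendered with fixed [0, 100] x [0, 100] axes and dashed
    reference lines at the thresholds.
    """
    if isinstance(reports, StrategyReport):
        reports = [reports]
    if not reports:
        raise GutDietError("no reports to export")

    frames = []
    for rep in reports:
        df = rep.to_frame()
        df.insert(0, "season", rep.season)
        df.insert(0, "species", rep.species)
        df["group_strategy"] = rep.group_label
        frames.append(df)
    coords = pd.concat(frames, ignore_index=True)
    for col in ("frequency_of_occurrence", "prey_specific_abundance", "importance_score"):
        coords[col] = coords[col].map(lambda v: round_half_up(v, digits))
    coords.to_csv(coords_path, sep="\t", index=False, float_format=f"%.{digits}f")

    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(reports)
        ncols = min(n, 2)
        nrows = -(-n // ncols)
        fig, axes = plt.subplots(
            nrows, ncols, figsize=(5.0 * ncols, 4.2 * nrows), squeeze=False
        )
        for ax in axes.ravel()[n:]:
            ax.set_visible(False)
        for ax, rep in zip(axes.ravel(), reports):
            xs = [p.frequency for p in rep.points]
            ys = [p.prey_specific_abundance for p in rep.points]
            ax.scatter(xs, ys, s=30, color="tab:blue", zorder=3)
            for p in rep.points:
                ax.annotate(
                    p.prey,
                    (p.frequency, p.prey_specific_abundance),
                    fontsize=7,
                    xytext=(3, 3),
                    textcoords="offset points",
                )
            ax.axhline(rep.y_threshold, ls="--", lw=0.8, color="grey")
            ax.axvline(rep.x_threshold, ls="--", lw=0.8, color="grey")
            ax.set_xlim(0, 100)
            ax.set_ylim(0, 100)
            ax.set_xlabel("Frequency of occurrence $F_i$ (%)")
            ax.set_ylabel("Prey-specific abundance $P_i$ (%)")
            ax.set_title(f"{rep.species} — {rep.season} ({rep.group_label})", fontsize=10)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return coords
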