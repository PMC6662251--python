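#!/usr/bin/env python
"""Amundsen-Costello feeding-strategy diagrams for the synthetic study.

Plots prey-specific abundance (P_i) against frequency of occurrence
(F_i) per prey for each species x season group, classifies each prey by
diagram quadrant (dominant/rare, specialization/generalization,
BPC/WPC), and labels each group's overall strategy.
"""

import runpy
from pathlib import Path

from gutdiet import (
    GUDGEON_POLICY,
    apply_exclusions,
    build_diet_matrix,
    classify_points,
    costello_points,
    export_diagram,
    filter_juveniles,
    prey_importance,
    read_diet_records,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    diet_file = RESULTS / "synthetic_diet.tsv"
    if not diet_file.exists():
        runpy.run_path(str(Path(__file__).with_name("01_simulate_study.py")), run_name="__main__")
    table = read_diet_records(diet_file)
    table = filter_juveniles(apply_exclusions(table, GUDGEON_POLICY), GUDGEON_POLICY)

    reports = []
    for mat in build_diet_matrix(table):
        imp = prey_importance(mat)
        rep = classify_points(
            costello_points(imp), species=imp.species, season=imp.season
        )
        reports.append(rep)
        print(f"{rep.species} ({rep.season}): {rep.group_label}")

    figures = RESULTS / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    export_diagram(
        reports,
        figures / "feeding_strategy.png",
        RESULTS / "synthetic_feeding_strategy_coords.tsv",
    )
    print(f"wrote {RESULTS / 'synthetic_feeding_strategy_coords.tsv'} and the figure panel")


if __name__ == "__main__":
    main()
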