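"""Packaged transcriptions of the published gudgeon diet tables.

Two small fixtures ship with the package:

* ``table1_specimens.tsv`` — specimen counts and standard-length
  summaries per species x season (8 groups, 936 fish in total);
* ``table2_diet_composition.tsv`` — per-prey frequency of occurrence
  (F_i) and relative abundance (A_i, percent by weight) per group, as
  printed at 2 decimal places.

The published A_i columns are the input for recomputing the pairwise
Schoener overlap table and Levins' breadth; the raw specimen-level data
were never deposited, so the composition table is an input here, not a
reproduction target.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .indices import DietProportions, NicheBreadth, OverlapMatrix, diet_proportions, levins_breadth, overlap_matrix

SPECIES = (
    "Coreius guichenoti",
    "Coreius heterodon",
    "Rhinogobio ventralis",
    "Rhinogobio cylindricus",
)
SEASONS = ("spring", "autumn")


def _read(name: str) -> pd.DataFrame:
    with resources.files("gutdiet.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_specimen_summary() -> pd.DataFrame:
    """Published specimen accounting (n, length mean/SE/range per group)."""
    return _read("table1_specimens.tsv")


def load_diet_composition() -> pd.DataFrame:
    """Published per-group diet composition (long format: F_i and A_i)."""
    return _read("table2_diet_composition.tsv")


def composition_proportions(
    species: str, season: str, renormalize: bool = False
) -> DietProportions:
    """Percent-by-weight diet proportions of one published group.

    By default the printed A_i column is used exactly as printed (sums
    lie in 99.99-100.01 from 2-dp rounding), which is how the published
    overlap table reproduces; pass ``renormalize=True`` to rescale to
    exactly 100.
    """
    df = load_diet_composition()
    sub = df[(df["species"] == species) & (df["season"] == season)]
    if sub.empty:
        raise KeyError(f"no published composition for {(species, season)}")
    p = pd.Series(sub["relative_abundance"].to_numpy(), index=sub["prey"].to_numpy())
    return diet_proportions(p, renormalize=renormalize, species=species, season=season)


def season_proportions(season: str, renormalize: bool = False) -> list[DietProportions]:
    """Published diet proportions of all four species in one season."""
    return [composition_proportions(sp, season, renormalize) for sp in SPECIES]


def published_overlaps(season: str, renormalize: bool = False) -> OverlapMatrix:
    """Recompute the pairwise Schoener overlap matrix for one season."""
    return overlap_matrix(season_proportions(season, renormalize))


def published_breadths(renormalize: bool = True) -> list[NicheBreadth]:
    """Levins' niche breadth per published group (Figure-3 analogue)."""
    return [
        levins_breadth(composition_proportions(sp, season, renormalize))
        for sp in SPECIES
        for season in SEASONS
    ]
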