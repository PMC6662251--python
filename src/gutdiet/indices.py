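"""Prey-importance, niche-breadth, and diet-overlap statistics.

For a group of fish (one species in one season) with N non-empty guts:

* frequency of occurrence   ``F_i = 100 * N_i / N``
* relative abundance        ``A_i = 100 * S_i / S_t``
* prey-specific abundance   ``P_i = 100 * S_i / St_i``

where ``N_i`` is the number of guts containing prey i, ``S_i`` the total
weight of prey i, ``S_t`` the total content weight of all examined guts,
and ``St_i`` the total content weight of only those guts containing prey
i.  P_i >= A_i always, with equality iff every non-empty gut contains i.

Diet overlap between two groups with percent-by-weight proportion
vectors p and q (union of prey categories, absent = 0) is Schoener's

    ``D = 100 - 0.5 * sum_i |p_i - q_i|``

which equals ``sum_i min(p_i, q_i)`` when both vectors sum to 100.
Overlap above 60% is conventionally called significant.  Dietary niche
breadth is Levins' ``B = 1 / sum_i p_i**2`` on the fraction scale,
ranging from 1 (monophagy) to S, the number of prey used.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import EmptyGroupError, GutDietError, ValidationError
from .io import DietMatrix

#: Overlap (percent) above which two diets are conventionally called
#: significantly overlapping.
SIGNIFICANT_OVERLAP = 60.0

#: How far a percent vector's sum may stray from 100 before it is rejected.
#: 2-dp printed tables accumulate at most a few hundredths of rounding error;
#: 0.5 also admits small tables whose minor prey were truncated.
SUM_TOLERANCE = 0.5


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed diet tables).

    The value is first snapped to 6 decimals so that binary float noise
    (~1e-12) cannot flip a half-way case.
    """
    q = Decimal(10) ** -digits
    return float(Decimal(f"{x:.6f}").quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PreyImportanceTable:
    """Per-prey F_i, A_i, P_i (percent) for one (species, season) group."""

    species: str
    season: str
    frame: pd.DataFrame  # index: prey; columns: F, A, P
    N: int

    @property
    def group_key(self) -> tuple[str, str]:
        return (self.species, self.season)


@dataclass(frozen=True)
class DietProportions:
    """Percent-by-weight diet composition of one group."""

    species: str
    season: str
    p: pd.Series  # index: prey; values: percent

    @property
    def group_key(self) -> tuple[str, str]:
        return (self.species, self.season)

    @property
    def label(self) -> str:
        return f"{self.species} ({self.season})"


@dataclass(frozen=True)
class NicheBreadth:
    """Levins' dietary niche breadth B and prey richness S for one group."""

    species: str
    season: str
    B: float
    S: int


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric pairwise Schoener overlap (percent) among groups."""

    values: pd.DataFrame  # square, labels x labels
    threshold: float = SIGNIFICANT_OVERLAP

    def significant_pairs(self) -> list[tuple[str, str, float]]:
        """Off-diagonal pairs whose overlap exceeds the threshold."""
        out = []
        labels = list(self.values.index)
        for a, b in combinations(labels, 2):
            d = float(self.values.loc[a, b])
            if d > self.threshold:
                out.append((a, b, d))
        return out


def prey_importance(matrix: DietMatrix) -> PreyImportanceTable:
    """Compute F_i, A_i, P_i for every prey observed in a group.

    Raises
    ------
    EmptyGroupError
        If no fish in the group has any gut content (N = 0).
    """
    N = matrix.N
    if N == 0:
        raise EmptyGroupError(
            f"group {matrix.group_key}: no fish with gut contents (N = 0)"
        )
    S_i = matrix.S_i
    observed = S_i[S_i > 0].index
    F = 100.0 * matrix.N_i[observed] / N
    A = 100.0 * S_i[observed] / matrix.S_t
    P = 100.0 * S_i[observed] / matrix.St_i[observed]
    frame = pd.DataFrame({"F": F, "A": A, "P": P})
    frame.index.name = "prey_category"
    return PreyImportanceTable(
        species=matrix.species, season=matrix.season, frame=frame, N=N
    )


def diet_proportions(
    source: DietMatrix | PreyImportanceTable | pd.Series,
    *,
    renormalize: bool = True,
    species: str = "",
    season: str = "",
) -> DietProportions:
    """Percent-by-weight diet proportions of one group.

    Accepts a raw weight matrix, a prey-importance table (its A column),
    or a bare percent series — the latter is the pathway for published
    relative-abundance columns.  With ``renormalize`` (default) the
    vector is scaled to sum exactly 100, which bounds rounding error
    from 2-dp printed inputs and makes the two algebraic forms of
    Schoener's D coincide; pass ``renormalize=False`` to audit published
    values exactly as printed.
    """
    if isinstance(source, DietMatrix):
        total = source.S_t
        if total <= 0:
            raise EmptyGroupError(f"group {source.group_key}: zero total content weight")
        p = 100.0 * source.S_i / total
        species, season = source.species, source.season
    elif isinstance(source, PreyImportanceTable):
        p = source.frame["A"].copy()
        species, season = source.species, source.season
    else:
        p = pd.Series(source, dtype=float)
    p = p[p > 0]
    total = float(p.sum())
    if total <= 0:
        raise GutDietError("diet proportions: all-zero input")
    if abs(total - 100.0) > SUM_TOLERANCE:
        raise ValidationError(
            f"diet proportions for {(species, season)} sum to {total:.4f}, not ~100"
        )
    if renormalize:
        p = p * (100.0 / total)
    p.index.name = "prey_category"
    return DietProportions(species=species, season=season, p=p)


def _check_percent_vector(p: pd.Series, label: str) -> None:
    if (p < 0).any():
        raise ValidationError(f"{label}: negative proportion")
    total = float(p.sum())
    if abs(total - 100.0) > SUM_TOLERANCE:
        raise ValidationError(f"{label}: proportions sum to {total:.4f}, not ~100")


def schoener_overlap(p: DietProportions | pd.Series, q: DietProportions | pd.Series) -> float:
    """Schoener's diet similarity D (percent) between two groups.

    The two proportion vectors are aligned on the union of their prey
    categories with absent prey as 0 before the half-sum of absolute
    differences is taken.
    """
    ps = p.p if isinstance(p, DietProportions) else pd.Series(p, dtype=float)
    qs = q.p if isinstance(q, DietProportions) else pd.Series(q, dtype=float)
    _check_percent_vector(ps, getattr(p, "label", "p"))
    _check_percent_vector(qs, getattr(q, "label", "q"))
    union = ps.index.union(qs.index)
    pa = ps.reindex(union, fill_value=0.0).to_numpy()
    qa = qs.reindex(union, fill_value=0.0).to_numpy()
    return float(100.0 - 0.5 * np.abs(pa - qa).sum())


def overlap_matrix(
    groups: list[DietProportions], threshold: float = SIGNIFICANT_OVERLAP
) -> OverlapMatrix:
    """All pairwise Schoener overlaps among >= 2 groups (diagonal = 100)."""
    if len(groups) < 2:
        raise GutDietError("overlap matrix needs at least two groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise GutDietError(f"duplicate group labels: {labels}")
    values = pd.DataFrame(100.0, index=labels, columns=labels)
    for (i, gi), (j, gj) in combinations(enumerate(groups), 2):
        d = schoener_overlap(gi, gj)
        values.iloc[i, j] = d
        values.iloc[j, i] = d
    return OverlapMatrix(values=values, threshold=threshold)


def levins_breadth(p: DietProportions | pd.Series) -> NicheBreadth:
    """Levins' dietary niche breadth B = 1 / sum(p_i^2) on fractions.

    Scale-invariant: percent and fraction inputs give the same B.  B is
    1 for a single-prey diet and S for a uniform diet over S prey.
    """
    ps = p.p if isinstance(p, DietProportions) else pd.Series(p, dtype=float)
    ps = ps[ps > 0]
    total = float(ps.sum())
    if total <= 0:
        raise GutDietError("Levins' breadth: zero diet vector")
    frac = ps.to_numpy() / total
    B = float(1.0 / np.square(frac).sum())
    species = getattr(p, "species", "")
    season = getattr(p, "season", "")
    return NicheBreadth(species=species, season=season, B=B, S=int(len(frac)))
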