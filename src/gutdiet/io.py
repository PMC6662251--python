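"""Reading, validating, and filtering individual-level gut-content records.

The raw analysis input is a long-format table: one row per fish x prey
category, carrying specimen metadata (species, season, standard length,
body weight) alongside the weight and count of that prey in the gut.  A
specimen with an empty gut is represented by a single row whose
``prey_category`` is blank and whose ``prey_weight`` is empty or zero, so
that the specimen survives a file round trip.

Filtering reproduces the specimen-handling rules of gut-content studies:
unidentifiable material and suspected parasites (e.g. cestodes) are
quantified but dropped before any index is computed, and juveniles are
removed by a per-species standard-length threshold (strictly "bigger
than") to avoid ontogenetic diet shifts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Columns a long-format diet file must provide.
REQUIRED_COLUMNS = (
    "fish_id",
    "species",
    "season",
    "standard_length",
    "prey_category",
    "prey_weight",
)
#: Columns carried through when present.
OPTIONAL_COLUMNS = ("body_weight", "prey_count")

_SPECIMEN_COLUMNS = ["fish_id", "species", "season", "standard_length", "body_weight"]
_CONTENT_COLUMNS = ["fish_id", "prey_category", "prey_weight", "prey_count"]


@dataclass(frozen=True)
class DietTable:
    """Validated individual-level diet observations.

    Attributes
    ----------
    specimens
        One row per fish: ``fish_id, species, season, standard_length,
        body_weight``.  Every examined specimen appears here, including
        those with empty guts.
    contents
        One row per (fish, prey) observation: ``fish_id, prey_category,
        prey_weight, prey_count``.  Fish with empty guts have no rows.
    """

    specimens: pd.DataFrame
    contents: pd.DataFrame

    @property
    def n_fish(self) -> int:
        return len(self.specimens)

    @property
    def n_records(self) -> int:
        """Number of (fish, prey) observations."""
        return len(self.contents)

    def fish_with_contents(self) -> pd.Index:
        return pd.Index(self.contents["fish_id"].unique())

    def to_frame(self) -> pd.DataFrame:
        """Flatten back to the long file layout (empty guts as blank rows)."""
        merged = self.specimens.merge(self.contents, on="fish_id", how="left")
        merged["prey_category"] = merged["prey_category"].fillna("")
        return merged[list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)]

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class ExclusionPolicy:
    """Prey-category exclusions and per-species juvenile length thresholds.

    ``min_length_by_species`` maps species to the standard length (mm)
    a specimen must strictly exceed to enter the analysis.
    """

    unidentifiable_labels: frozenset[str] = frozenset({"Unidentified"})
    parasite_labels: frozenset[str] = frozenset({"Cestoda"})
    min_length_by_species: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "unidentifiable_labels", frozenset(self.unidentifiable_labels))
        object.__setattr__(self, "parasite_labels", frozenset(self.parasite_labels))
        for sp, thr in self.min_length_by_species.items():
            if not thr > 0:
                raise ConfigurationError(f"length threshold for {sp!r} must be positive, got {thr}")

    @property
    def excluded_labels(self) -> frozenset[str]:
        return self.unidentifiable_labels | self.parasite_labels


#: Juvenile length thresholds (mm standard length) for the four gudgeon
#: species of the upper-Yangtze study; specimens must be strictly larger.
GUDGEON_POLICY = ExclusionPolicy(
    unidentifiable_labels=frozenset({"Unidentified"}),
    parasite_labels=frozenset({"Cestoda"}),
    min_length_by_species={
        "Coreius guichenoti": 96.0,
        "Coreius heterodon": 139.0,
        "Rhinogobio ventralis": 79.0,
        "Rhinogobio cylindricus": 114.0,
    },
)


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_diet_records(path: str | Path, sep: str | None = None) -> DietTable:
    """Read and validate a long-format diet file.

    Parameters
    ----------
    path
        Delimited text file with a header row.  Tab-separated unless the
        suffix is ``.csv`` or ``sep`` is given.
    sep
        Explicit field delimiter.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If rows violate record invariants; the offending 1-based file
        rows (header = row 1) are listed in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype={"fish_id": str, "prey_category": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return diet_table_from_frame(df, source=path.name)


def diet_table_from_frame(df: pd.DataFrame, source: str = "<frame>") -> DietTable:
    """Validate a long-format DataFrame and split it into a :class:`DietTable`."""
    df = df.copy().reset_index(drop=True)
    # 1-based file rows: header occupies row 1.
    file_rows = df.index + 2

    df["prey_category"] = df["prey_category"].fillna("").astype(str).str.strip()
    empty = df["prey_category"] == ""

    bad_weight = (~empty) & ((df["prey_weight"].isna()) | (df["prey_weight"] < 0))
    if bad_weight.any():
        raise ValidationError(
            f"{source}: prey_weight must be >= 0 and present for prey rows",
            rows=list(file_rows[bad_weight]),
        )
    bad_len = df["standard_length"].isna() | (df["standard_length"] <= 0)
    if bad_len.any():
        raise ValidationError(
            f"{source}: standard_length must be > 0", rows=list(file_rows[bad_len])
        )
    bad_count = df["prey_count"].notna() & (df["prey_count"] < 0)
    if bad_count.any():
        raise ValidationError(
            f"{source}: prey_count must be >= 0", rows=list(file_rows[bad_count])
        )
    dup = (~empty) & df.duplicated(subset=["fish_id", "prey_category"], keep=False)
    if dup.any():
        raise ValidationError(
            f"{source}: duplicate (fish_id, prey_category) pairs",
            rows=list(file_rows[dup]),
        )

    specimens = df.loc[:, [c for c in _SPECIMEN_COLUMNS if c in df.columns]].drop_duplicates(
        subset="fish_id"
    )
    conflicting = (
        df.groupby("fish_id")[["species", "season", "standard_length"]].nunique() > 1
    ).any(axis=1)
    if conflicting.any():
        bad_ids = conflicting[conflicting].index.tolist()
        raise ValidationError(f"{source}: conflicting specimen metadata for fish {bad_ids}")
    if "body_weight" not in specimens.columns:
        specimens = specimens.assign(body_weight=np.nan)
    specimens = specimens[_SPECIMEN_COLUMNS].reset_index(drop=True)

    contents = df.loc[~empty, [c for c in _CONTENT_COLUMNS if c in df.columns]].copy()
    if "prey_count" not in contents.columns:
        contents["prey_count"] = np.nan
    contents = contents[_CONTENT_COLUMNS].reset_index(drop=True)
    return DietTable(specimens=specimens, contents=contents)


def apply_exclusions(table: DietTable, policy: ExclusionPolicy) -> DietTable:
    """Drop unidentifiable and parasite prey rows.

    Specimens are never removed here: a fish whose only contents were
    excluded categories remains in the table with an (analytically)
    empty gut, and is later excluded from N — the count of fish with
    gut contents of any kind — by the matrix builder.
    """
    drop = table.contents["prey_category"].isin(policy.excluded_labels)
    n_dropped = int(drop.sum())
    if n_dropped:
        per_label = table.contents.loc[drop, "prey_category"].value_counts()
        for label, count in per_label.items():
            logger.info("excluded %d row(s) of %r", count, label)
    return replace(table, contents=table.contents.loc[~drop].reset_index(drop=True))


def filter_juveniles(table: DietTable, policy: ExclusionPolicy) -> DietTable:
    """Keep only specimens strictly larger than their species threshold."""
    species_present = set(table.specimens["species"].unique())
    missing = species_present - set(policy.min_length_by_species)
    if missing:
        raise ConfigurationError(
            f"no length threshold configured for species: {sorted(missing)}"
        )
    thr = table.specimens["species"].map(policy.min_length_by_species)
    keep = table.specimens["standard_length"] > thr
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d juvenile specimen(s)", n_removed)
    specimens = table.specimens.loc[keep].reset_index(drop=True)
    contents = table.contents[table.contents["fish_id"].isin(specimens["fish_id"])]
    return DietTable(specimens=specimens, contents=contents.reset_index(drop=True))


@dataclass
class DietMatrix:
    """Per-group fish-by-prey weight matrix (grams).

    Rows are every examined specimen of the group (empty guts included
    as all-zero rows); columns are the prey categories observed in the
    group.  All index denominators live here: ``N`` counts fish with any
    content, ``S_t`` is the total content weight, ``S_i``/``N_i``/
    ``St_i`` the per-prey weight, occurrence count, and total content
    weight of the fish containing prey i.
    """

    species: str
    season: str
    weights: pd.DataFrame  # index: fish_id, columns: prey categories

    @property
    def group_key(self) -> tuple[str, str]:
        return (self.species, self.season)

    @property
    def fish_totals(self) -> pd.Series:
        return self.weights.sum(axis=1)

    @property
    def N(self) -> int:
        """Number of fish with gut contents of any kind."""
        return int((self.fish_totals > 0).sum())

    @property
    def N_i(self) -> pd.Series:
        """Number of fish containing each prey."""
        return (self.weights > 0).sum(axis=0)

    @property
    def S_i(self) -> pd.Series:
        """Total weight of each prey across all guts (g)."""
        return self.weights.sum(axis=0)

    @property
    def S_t(self) -> float:
        """Total gut-content weight of all examined guts (g)."""
        return float(self.weights.to_numpy().sum())

    @property
    def St_i(self) -> pd.Series:
        """Total content weight of the fish whose guts contain each prey (g)."""
        present = (self.weights > 0).astype(float)
        return present.mul(self.fish_totals, axis=0).sum(axis=0)


def build_diet_matrix(
    table: DietTable, group_by: tuple[str, str] = ("species", "season")
) -> list[DietMatrix]:
    """Aggregate a filtered table into one weight matrix per group.

    The prey axis is the union of categories observed in the group,
    ordered by descending total weight (ties alphabetically).  Groups are
    returned in sorted key order.
    """
    matrices: list[DietMatrix] = []
    merged = table.contents.merge(table.specimens[["fish_id", *group_by]], on="fish_id")
    for key, spec_grp in table.specimens.groupby(list(group_by), sort=True):
        fish_ids = spec_grp["fish_id"]
        sub = merged[merged["fish_id"].isin(fish_ids)]
        if sub.empty:
            mat = pd.DataFrame(0.0, index=fish_ids, columns=pd.Index([], dtype=object))
        else:
            mat = (
                sub.pivot_table(
                    index="fish_id", columns="prey_category", values="prey_weight", aggfunc="sum"
                )
                .reindex(fish_ids)
                .fillna(0.0)
            )
            # descending weight, alphabetical among exact ties
            totals = mat.sum(axis=0)
            order = sorted(mat.columns, key=lambda c: (-totals[c], c))
            mat = mat[order]
        mat.index.name = "fish_id"
        mat.columns.name = "prey_category"
        matrices.append(DietMatrix(species=key[0], season=key[1], weights=mat))
    return matrices


def summarize_specimens(
    table: DietTable, group_by: tuple[str, str] = ("species", "season")
) -> pd.DataFrame:
    """Per-group specimen accounting: n, mean/SE/min/max standard length.

    SE is the sample standard deviation over sqrt(n); for singleton
    groups it is reported as 0 with a warning.
    """
    rows = []
    for key, grp in table.specimens.groupby(list(group_by), sort=True):
        lengths = grp["standard_length"].to_numpy(dtype=float)
        n = len(lengths)
        if n == 1:
            warnings.warn(
                f"group {key}: single specimen, standard error reported as 0",
                stacklevel=2,
            )
            se = 0.0
        else:
            se = float(np.std(lengths, ddof=1) / np.sqrt(n))
        rows.append(
            dict(
                zip(group_by, key),
                n=n,
                mean_standard_length_mm=float(np.mean(lengths)),
                se_standard_length_mm=se,
                min_standard_length_mm=float(np.min(lengths)),
                max_standard_length_mm=float(np.max(lengths)),
            )
        )
    return pd.DataFrame(rows)
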