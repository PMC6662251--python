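import pandas as pd
import pytest

from gutdiet import DietTable, build_diet_matrix, diet_table_from_frame

LONG_COLUMNS = [
    "fish_id",
    "species",
    "season",
    "standard_length",
    "body_weight",
    "prey_category",
    "prey_weight",
    "prey_count",
]


def make_table(rows) -> DietTable:
    """Build a DietTable from (fish, species, season, length, prey, weight) tuples.

    An empty prey name marks an empty-gut specimen row.
    """
    df = pd.DataFrame(
        [(f, sp, se, ln, None, prey, w, None) for f, sp, se, ln, prey, w in rows],
        columns=LONG_COLUMNS,
    )
    return diet_table_from_frame(df)


@pytest.fixture
def fixture_w() -> DietTable:
    """Four-fish worked example: fish1 {A: 2 g}; fish2 {A: 1, B: 1};
    fish3 {B: 3}; fish4 empty.  Hand-derived indices: F_A = F_B = 66.67,
    A_A = 42.86, A_B = 57.14, P_A = 75, P_B = 80, Levins' B = 1.96."""
    return make_table(
        [
            ("f1", "S", "spring", 150.0, "A", 2.0),
            ("f2", "S", "spring", 150.0, "A", 1.0),
            ("f2", "S", "spring", 150.0, "B", 1.0),
            ("f3", "S", "spring", 150.0, "B", 3.0),
            ("f4", "S", "spring", 150.0, "", None),
        ]
    )


@pytest.fixture
def matrix_w(fixture_w):
    (mat,) = build_diet_matrix(fixture_w)
    return mat
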