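# gutdiet

Diet-composition and niche-overlap analysis for gut-content studies in
trophic ecology. The package implements the standard analysis chain used
to ask whether sympatric fish species partition food resources — built
around the four-gudgeon (Gobioninae) study system of the upper Yangtze
River, but generic over species, seasons, and prey categories.

Given individual-level gut contents (one row per fish × prey, with prey
weights), it computes, per species × season group:

- **prey importance** — frequency of occurrence `F_i = 100·N_i/N`,
  relative abundance `A_i = 100·S_i/S_t`, and prey-specific abundance
  `P_i = 100·S_i/St_i`;
- **Levins' dietary niche breadth** `B = 1/Σp_i²` (1 = monophagy, S =
  uniform use of S prey);
- **Schoener's pairwise diet overlap** `D = 100 − 0.5·Σ|p_i − q_i|` on
  percent-by-weight proportions, with the conventional 60% significance
  threshold;
- the **modified Costello (Amundsen) feeding-strategy diagram** (`P_i`
  vs `F_i` per prey), with quadrant classification into dominant/rare
  prey, specialized/generalized strategies, and between- vs
  within-phenotype niche components (BPC/WPC).

Specimen handling reproduces the field's rules: unidentifiable material
and suspected parasites are quantified but excluded from analysis,
juveniles are dropped by strict per-species length thresholds, and fish
with empty guts stay in the specimen accounting but leave `N`. A
seed-deterministic synthetic generator (occupancy × conditional
log-normal weights × phenotype mixtures) makes every stage testable
without raw specimen data, which the study never deposited. Transcribed
summary tables of the study (specimen counts; per-group `F_i`/`A_i`)
ship as packaged fixtures under `gutdiet.datasets`.

## Worked example

Four fish: fish1 ate 2 g of prey A; fish2 1 g of A and 1 g of B; fish3
3 g of B; fish4 had an empty gut (so `N = 3`).

```python
import pandas as pd
from gutdiet import (diet_table_from_frame, build_diet_matrix,
                     prey_importance, diet_proportions, levins_breadth)

rows = [("f1", "S", "spring", 150, None, "A", 2.0, None),
        ("f2", "S", "spring", 150, None, "A", 1.0, None),
        ("f2", "S", "spring", 150, None, "B", 1.0, None),
        ("f3", "S", "spring", 150, None, "B", 3.0, None),
        ("f4", "S", "spring", 150, None, "",  None, None)]   # empty gut
cols = ["fish_id", "species", "season", "standard_length", "body_weight",
        "prey_category", "prey_weight", "prey_count"]
table = diet_table_from_frame(pd.DataFrame(rows, columns=cols))
(mat,) = build_diet_matrix(table)
print(prey_importance(mat).frame.round(2))
print("B =", round(levins_breadth(diet_proportions(mat)).B, 2))
```

prints

```
                   F      A     P
prey_category
B              66.67  57.14  80.0
A              66.67  42.86  75.0
B = 1.96
```

Both prey occur in 2 of the 3 non-empty guts (`F = 66.67`); prey B is
57.14% of the 7 g total content but 80% of the content of the guts that
contain it (`P ≥ A` always); a breadth of 1.96 sits near the two-prey
maximum of 2, i.e. an evenly split diet.

The same pipeline is scriptable from the shell (`gutdiet simulate |
indices | overlap | strategy`), and the numbered drivers under
`analysis/` run the full study-shaped analysis: `01` simulates a
936-fish, 8-group synthetic analogue of the gudgeon study, `02` computes
importance and breadth tables, `03` recomputes the published overlap
matrices, and `04` renders the feeding-strategy panels into `results/`.

Running `analysis/03_diet_overlap.py` prints, from the packaged
composition columns:

```
spring: 6/6 pairs exceed 60%
  ...
  Coreius heterodon (spring) vs Rhinogobio ventralis (spring): D = 82.65
autumn: 4/6 pairs exceed 60%
  ...
  Coreius heterodon (autumn) vs Rhinogobio ventralis (autumn): D = 98.38
```

— the study's headline pattern: uniformly high overlap in spring, and
in autumn two species diversify away while *C. heterodon* and
*R. ventralis* converge on near-complete overlap.

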