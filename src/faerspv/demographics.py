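"""Age and gender association with taste/smell disorders on Table B.

Patients are dichotomized (age at a cutoff, default 70 years; or gender)
and each split is analyzed with the same ROR / Fisher / Wald machinery as
the per-drug screening.  Demographic cells are large and zero-free, so
the ROR and CI use the uncorrected counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .disproportionality import (
    ContingencyTable2x2,
    DisproportionalityResult,
    association,
)
from .errors import DegenerateDataError

DEFAULT_AGE_CUTOFF = 70.0


@dataclass(frozen=True)
class StratumSplit:
    """A two-group split of Table B with its group-by-outcome 2x2 counts.

    ``table.a`` counts group-1 cases (e.g. age >= 70 with a taste/smell
    disorder); group 1 plays the exposure row.
    """

    label: str
    group1: str
    group2: str
    table: ContingencyTable2x2


def dichotomize(
    table_b: pd.DataFrame, variable: str, cutoff: float = DEFAULT_AGE_CUTOFF
) -> StratumSplit:
    """Split Table B rows by age (>= cutoff vs below) or gender (M vs F)."""
    if variable == "age":
        if not 0.0 < cutoff <= 120.0:
            raise ValueError(f"age cutoff {cutoff} outside (0, 120]")
        in_group1 = table_b["age_years"] >= cutoff
        g1, g2 = f"age>={cutoff:g}", f"age<{cutoff:g}"
        label = f"age at {cutoff:g} years"
    elif variable == "gender":
        in_group1 = table_b["gender"] == "M"
        g1, g2 = "male", "female"
        label = "gender"
    else:
        raise ValueError(f"unknown stratification variable {variable!r}")

    tsd = table_b["tsd"].astype(bool)
    a = int((in_group1 & tsd).sum())
    b = int((in_group1 & ~tsd).sum())
    c = int((~in_group1 & tsd).sum())
    d = int((~in_group1 & ~tsd).sum())
    return StratumSplit(label=label, group1=g1, group2=g2,
                        table=ContingencyTable2x2(a, b, c, d))


def stratum_association(split: StratumSplit, level: float = 0.95) -> DisproportionalityResult:
    """ROR, Fisher p, and Wald CI for a stratum split (uncorrected counts)."""
    t = split.table
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        raise DegenerateDataError(
            f"{split.label}: a zero marginal leaves the association undefined"
        )
    return association(t, entity=split.group1, haldane=False, level=level)


def demographic_table(
    splits: Sequence[StratumSplit], level: float = 0.95
) -> pd.DataFrame:
    """One row per group, in the shape of a published demographics table."""
    rows = []
    for split in splits:
        res = stratum_association(split, level=level)
        t = split.table
        rows.append(
            {
                "variable": split.label,
                "group": split.group1,
                "tsd": int(t.a),
                "non_tsd": int(t.b),
                "p": res.p,
                "ror": res.ror,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
        rows.append(
            {
                "variable": split.label,
                "group": split.group2,
                "tsd": int(t.c),
                "non_tsd": int(t.d),
                "p": None,
                "ror": None,
                "ci_low": None,
                "ci_high": None,
            }
        )
    return pd.DataFrame(rows)


def write_demographic_csv(
    splits: Sequence[StratumSplit], path: str | Path, level: float = 0.95
) -> None:
    demographic_table(splits, level=level).to_csv(path, index=False)
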